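import numpy as np
import pytest

from surgact import DecodingError, ExplicitDurationHSMM, map_init_emissions
from surgact.states import Segmentation

from oracles import brute_force_decode, random_hsmm


def two_state_model(**kw):
    defaults = dict(
        states=("a", "b"),
        startprob=[1.0, 0.0],
        transmat=[[0.0, 1.0], [1.0, 0.0]],
        duration_params=[(2.0, 0.5), (2.0, 0.5)],
        d_max=4,
        emissions=[[[1.0, 0.0]], [[0.0, 1.0]]],
    )
    defaults.update(kw)
    return ExplicitDurationHSMM(**defaults)


class TestDurationPmf:
    def test_geometric_special_case(self):
        m = ExplicitDurationHSMM(
            states=("a",), startprob=[1.0], transmat=[[0.0]],
            duration_params=[(1.0, 0.5)], d_max=5000, emissions=[[[1.0]]],
        )
        # r=1: shifted geometric, pmf(d) = 0.5^d
        assert m.duration_pmf("a", 1) == pytest.approx(0.5, abs=1e-12)
        assert m.duration_pmf("a", 3) == pytest.approx(0.125, abs=1e-12)

    def test_closed_form_nb_value(self):
        m = ExplicitDurationHSMM(
            states=("a",), startprob=[1.0], transmat=[[0.0]],
            duration_params=[(2.0, 0.5)], d_max=10_000, emissions=[[[1.0]]],
        )
        # d=3 is k=2 failures: C(3,1) * 0.5^2 * 0.25 = 0.1875
        assert m.duration_pmf("a", 3) == pytest.approx(0.1875, rel=1e-9)

    @pytest.mark.parametrize("r,p,d_max", [(1.0, 0.5, 3), (2.7, 0.3, 17), (0.6, 0.9, 1)])
    def test_truncated_pmf_sums_to_one(self, r, p, d_max):
        m = ExplicitDurationHSMM(
            states=("a",), startprob=[1.0], transmat=[[0.0]],
            duration_params=[(r, p)], d_max=d_max, emissions=[[[1.0]]],
        )
        total = sum(m.duration_pmf("a", d) for d in range(1, d_max + 1))
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_out_of_range_duration(self):
        m = two_state_model()
        with pytest.raises(ValueError):
            m.duration_pmf("a", 0)
        with pytest.raises(ValueError):
            m.duration_pmf("a", 99)


class TestMapInitEmissions:
    def test_uniform_prior_gives_empirical_frequencies(self):
        labels = np.array([0, 0, 0])
        sensors = np.array([[0], [0], [2]])
        B = map_init_emissions(labels, sensors, alpha=1.0, n_states=1, n_symbols=[3])
        assert np.allclose(B[0][0], [2 / 3, 0.0, 1 / 3])

    def test_alpha_two_matches_map_formula(self):
        # counts (2, 0, 1) with alpha=(2,2,2): (n + 1) / (N + 3) = (3,1,2)/6
        labels = np.array([0, 0, 0])
        sensors = np.array([[0], [0], [2]])
        B = map_init_emissions(labels, sensors, alpha=2.0, n_states=1, n_symbols=[3])
        assert np.allclose(B[0][0], [3 / 6, 1 / 6, 2 / 6])

    def test_unseen_state_falls_back_to_prior_mode(self):
        labels = np.array([0, 0])
        sensors = np.array([[0], [1]])
        B = map_init_emissions(labels, sensors, alpha=2.0, n_states=2, n_symbols=[2])
        assert np.allclose(B[1][0], [0.5, 0.5])

    def test_boundary_alpha_rejected(self):
        with pytest.raises(ValueError):
            map_init_emissions(np.array([0]), np.array([[0]]), alpha=0.5,
                               n_states=1, n_symbols=[2])

    def test_unseen_state_with_flat_prior_rejected(self):
        labels = np.array([0])
        sensors = np.array([[0]])
        with pytest.raises(ValueError, match="regularizing"):
            map_init_emissions(labels, sensors, alpha=1.0, n_states=2, n_symbols=[2])

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(0)
        labels = rng.integers(0, 3, 50)
        sensors = rng.integers(0, 4, (50, 2))
        B = map_init_emissions(labels, sensors, alpha=1.5, n_states=3, n_symbols=[4, 4])
        for s in range(3):
            for c in range(2):
                assert np.isclose(B[s][c].sum(), 1.0, atol=1e-12)


class TestViterbi:
    def test_single_state_single_interval(self):
        m = ExplicitDurationHSMM(
            states=("only",), startprob=[1.0], transmat=[[0.0]],
            duration_params=[(2.0, 0.5)], d_max=10, emissions=[[[0.6, 0.4]]],
        )
        obs = np.array([[0], [1], [0], [0]])
        seg, logp = m.decode(obs)
        assert seg.intervals == [(0, 0, 4)]
        assert np.isfinite(logp)

    def test_two_state_deterministic_emissions(self):
        m = two_state_model()
        seg, _ = m.decode(np.array([[0], [0], [1], [1]]))
        assert seg.intervals == [(0, 0, 2), (1, 2, 4)]

    def test_unseen_symbol_raises(self):
        m = two_state_model()
        with pytest.raises(DecodingError, match="frame"):
            m.decode(np.array([[0], [2]]))

    def test_zero_probability_symbol_identifies_position(self):
        m = two_state_model(emissions=[[[1.0, 0.0, 0.0]], [[0.0, 1.0, 0.0]]])
        with pytest.raises(DecodingError, match="channel 0"):
            m.decode(np.array([[0], [2]]))

    def test_epsilon_smoothing_recovers(self):
        m = two_state_model(
            emissions=[[[1.0, 0.0, 0.0]], [[0.0, 1.0, 0.0]]],
            unseen_smoothing=1e-8,
        )
        seg, _ = m.decode(np.array([[0], [2], [1], [1]]))
        assert seg.n_frames == 4

    def test_empty_observation_rejected(self):
        with pytest.raises(ValueError):
            two_state_model().decode(np.empty((0, 1), dtype=int))

    def test_symbol_relabeling_invariance(self):
        # permuting symbol codes consistently in tables and stream leaves
        # the decoded segmentation unchanged
        rng = np.random.default_rng(5)
        m = random_hsmm(rng, n_states=3, n_channels=1, d_max=4)
        _, obs = m.sample(12, random_state=9)
        seg, logp = m.decode(obs)
        K = len(m.emissions[0][0])
        perm = rng.permutation(K)
        inv = np.argsort(perm)
        m2 = ExplicitDurationHSMM(
            states=m.states, startprob=m.startprob, transmat=m.transmat,
            duration_params=m.duration_params, d_max=m.d_max,
            emissions=[[np.asarray(chan)[perm] for chan in st] for st in m.emissions],
        )
        seg2, logp2 = m2.decode(inv[obs])
        assert seg2.intervals == seg.intervals
        assert logp2 == pytest.approx(logp, abs=1e-9)

    def test_constant_channel_does_not_change_decoding(self):
        rng = np.random.default_rng(6)
        m = random_hsmm(rng, n_states=3, n_channels=1, d_max=4)
        _, obs = m.sample(10, random_state=11)
        seg, _ = m.decode(obs)
        m2 = ExplicitDurationHSMM(
            states=m.states, startprob=m.startprob, transmat=m.transmat,
            duration_params=m.duration_params, d_max=m.d_max,
            emissions=[st + [np.array([1.0])] for st in m.emissions],
        )
        seg2, _ = m2.decode(np.c_[obs, np.zeros(len(obs), dtype=int)])
        assert seg2.intervals == seg.intervals


class TestForward:
    def test_single_state_closed_form(self):
        m = ExplicitDurationHSMM(
            states=("only",), startprob=[1.0], transmat=[[0.0]],
            duration_params=[(2.0, 0.5)], d_max=10, emissions=[[[0.6, 0.4]]],
        )
        obs = np.array([[0], [1], [0]])
        expected = np.log(m.duration_pmf("only", 3)) + 2 * np.log(0.6) + np.log(0.4)
        assert m.score(obs) == pytest.approx(expected, abs=1e-12)

    def test_loglik_upper_bounds_viterbi(self):
        rng = np.random.default_rng(12)
        for _ in range(10):
            m = random_hsmm(rng)
            tau = int(rng.integers(1, 8))
            if len(m.states) == 1:
                tau = min(tau, m.d_max)
            _, obs = m.sample(tau, random_state=int(rng.integers(1e6)))
            _, lp = m.decode(obs)
            assert m.score(obs) >= lp - 1e-10


class TestOracleEquivalence:
    def test_small_random_instances_match_enumeration(self):
        """Viterbi and forward equal exhaustive enumeration on 60 random specs."""
        rng = np.random.default_rng(2024)
        for _ in range(60):
            m = random_hsmm(rng)
            tau = int(rng.integers(1, 9))
            if len(m.states) == 1:
                tau = min(tau, m.d_max)
            _, obs = m.sample(tau, random_state=int(rng.integers(1e6)))
            seg, lp = m.decode(obs)
            best_runs, best_score, total = brute_force_decode(m, obs)
            assert lp == pytest.approx(best_score, abs=1e-9)
            assert m.score(obs) == pytest.approx(total, abs=1e-9)


class TestSampling:
    def test_fixed_seed_determinism(self):
        m = two_state_model()
        s1 = m.sample(30, random_state=3)
        s2 = m.sample(30, random_state=3)
        assert s1[0].intervals == s2[0].intervals
        assert np.array_equal(s1[1], s2[1])

    def test_initial_state_frequencies(self):
        m = two_state_model(startprob=[0.3, 0.7])
        rng = np.random.default_rng(0)
        firsts = [m.sample(2, random_state=int(rng.integers(1e9)))[0].intervals[0][0]
                  for _ in range(10_000)]
        f = np.mean(np.array(firsts) == 0)
        se = np.sqrt(0.3 * 0.7 / 10_000)
        assert abs(f - 0.3) < 3 * se

    def test_segments_respect_d_max(self):
        m = two_state_model(d_max=3)
        seg, _ = m.sample(50, random_state=8)
        assert max(e - s for _, s, e in seg.intervals) <= 3

    def test_bad_max_frames(self):
        with pytest.raises(ValueError):
            two_state_model().sample(0)


class TestParameterRecovery:
    def test_decoding_with_true_spec_recovers_labels(self):
        """Well-separated emissions: frame accuracy >= 0.9 on sampled data."""
        rng = np.random.default_rng(0)
        S = 4
        A = np.zeros((S, S))
        for i in range(S):
            A[i, [j for j in range(S) if j != i]] = rng.dirichlet(np.ones(S - 1))
        emissions = []
        for s in range(S):
            tab = np.full(6, 0.1 / 5)
            tab[s] = 0.9  # pairwise TV distance 0.9 >= 0.5
            emissions.append([tab])
        m = ExplicitDurationHSMM(
            states=tuple("abcd"), startprob=np.full(S, 0.25), transmat=A,
            duration_params=[(5.0, 0.5)] * S, emissions=emissions,
        )
        accs = []
        for i in range(10):
            seg, obs = m.sample(300, random_state=100 + i)
            accs.append(np.mean(m.predict(obs) == seg.to_labels()))
        assert np.mean(accs) >= 0.9


class TestSerialization:
    def test_json_roundtrip_preserves_inference(self, tmp_path):
        rng = np.random.default_rng(1)
        m = random_hsmm(rng, n_states=3, n_channels=2, d_max=4)
        _, obs = m.sample(8, random_state=4)
        path = tmp_path / "spec.json"
        m.to_json(path)
        m2 = ExplicitDurationHSMM.from_json(path)
        assert m2.states == m.states
        assert m2.decode(obs)[0].intervals == m.decode(obs)[0].intervals
        assert m2.score(obs) == pytest.approx(m.score(obs), abs=1e-12)


def test_fit_estimates_emissions_for_decoding(toy_cohort):
    cfg, trajectories = toy_cohort
    ann = trajectories[0]
    from surgact import expert_hsmm

    model = expert_hsmm(cfg)
    model.fit(ann.activities, ann.sensors, n_symbols=cfg.channel_sizes())
    labels = model.predict(trajectories[1].sensors)
    assert labels.shape == trajectories[1].activities.shape
    seg = Segmentation.from_labels(labels)
    assert seg.n_frames == trajectories[1].total_length
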