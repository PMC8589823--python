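import hashlib
import json

import numpy as np
import pytest
from scipy.stats import nbinom

from surgact import GeneratorConfig, generate_dataset, generate_trajectory
from surgact.synthetic import (
    ConfigError,
    GenerationError,
    planted_event_times,
    render_sensor_stream,
    render_video,
    sample_activity_sequence,
)


def small_config(**kw):
    kw.setdefault("n_trajectories", 3)
    kw.setdefault("seed", 7)
    return GeneratorConfig(**kw)


class TestConfigValidation:
    def test_initial_distribution_must_sum_to_one(self):
        with pytest.raises(ConfigError):
            small_config(initial_distribution={"diagnosis": 0.7})

    def test_self_loop_rejected(self):
        g = small_config().activity_graph
        g["cutting"] = g["cutting"] + ["cutting"]
        with pytest.raises(ConfigError):
            small_config(activity_graph=g)

    def test_bad_duration_params(self):
        cfg = small_config()
        with pytest.raises(ConfigError):
            small_config(duration_params={**cfg.duration_params, "cutting": (2.0, 1.5)})

    def test_ambiguity_pairs_share_tables_exactly(self):
        cfg = small_config()
        for a, b in cfg.ambiguity_pairs:
            for ta, tb in zip(cfg.sensor_spec[a], cfg.sensor_spec[b]):
                assert np.array_equal(ta, tb)


class TestActivitySequences:
    def test_starts_with_diagnosis_under_degenerate_initial(self):
        cfg = small_config()
        for i in range(20):
            labels = sample_activity_sequence(cfg, cfg.trajectory_rng(i))
            assert labels[0] == cfg.state_space.index("diagnosis")

    def test_no_consecutive_repeats(self):
        cfg = small_config()
        labels = sample_activity_sequence(cfg, cfg.trajectory_rng(0))
        runs = np.flatnonzero(np.diff(labels))
        states = labels[np.concatenate([[0], runs + 1])]
        assert all(a != b for a, b in zip(states, states[1:]))

    def test_transitions_respect_graph(self):
        cfg = small_config()
        sp = cfg.state_space
        labels = sample_activity_sequence(cfg, cfg.trajectory_rng(3))
        boundaries = np.flatnonzero(np.diff(labels))
        for b in boundaries:
            src, dst = sp.name(labels[b]), sp.name(labels[b + 1])
            assert dst in cfg.activity_graph[src]

    def test_geometric_special_case_mean(self):
        # single-activity graph, NB(r=1, p=0.5) durations: run lengths are
        # 1 + Geometric(0.5); closed-form mean 2 vs Monte Carlo
        cfg = GeneratorConfig(
            n_trajectories=1,
            state_space=small_config().state_space,
            activity_graph={s: [] for s in small_config().state_space.states},
            initial_distribution={"handle chips": 1.0},
            duration_params={s: (1.0, 0.5) for s in small_config().state_space.states},
            final_activity="handle chips",
            seed=5,
        )
        rng = np.random.default_rng(0)
        draws = np.array(
            [len(sample_activity_sequence(cfg, rng)) for _ in range(10_000)]
        )
        mean, se = draws.mean(), draws.std(ddof=1) / np.sqrt(draws.size)
        assert abs(mean - 2.0) < 3 * se

    def test_dead_end_raises_naming_activity(self):
        cfg = small_config()
        g = dict(cfg.activity_graph)
        g["position hysteroscope"] = []
        with pytest.raises(GenerationError, match="position hysteroscope"):
            bad = GeneratorConfig(n_trajectories=1, activity_graph=g, seed=1)
            sample_activity_sequence(bad, bad.trajectory_rng(0))


class TestSensorStream:
    def test_deterministic_tables_recode_activities(self):
        cfg = small_config()
        sp = cfg.state_space
        spec = {s: [np.eye(len(sp))[i]] for i, s in enumerate(sp.states)}
        det = GeneratorConfig(n_trajectories=1, sensor_spec=spec, ambiguity_pairs=[], seed=3)
        labels = sample_activity_sequence(det, det.trajectory_rng(0))
        stream = render_sensor_stream(labels, det, det.trajectory_rng(1))
        assert np.array_equal(stream[:, 0], labels)

    def test_empty_sequence_rejected(self):
        cfg = small_config()
        with pytest.raises(ValueError):
            render_sensor_stream(np.array([], dtype=int), cfg, cfg.trajectory_rng(0))

    def test_ambiguous_pair_distributions_converge(self):
        # diagnosis and position hysteroscope share tables: empirical symbol
        # frequencies from many frames of each agree within TV < 0.05
        cfg = small_config()
        sp = cfg.state_space
        rng = np.random.default_rng(8)
        n = 50_000
        lab = np.concatenate([np.zeros(n, dtype=int), np.ones(n, dtype=int)])
        stream = render_sensor_stream(lab, cfg, rng)
        for c in range(stream.shape[1]):
            K = cfg.channel_sizes()[c]
            f0 = np.bincount(stream[:n, c], minlength=K) / n
            f1 = np.bincount(stream[n:, c], minlength=K) / n
            assert 0.5 * np.abs(f0 - f1).sum() < 0.05

    def test_per_activity_frequencies_match_tables(self):
        cfg = small_config()
        rng = np.random.default_rng(9)
        n = 50_000
        for s in [2, 5]:
            stream = render_sensor_stream(np.full(n, s), cfg, rng)
            tables = cfg.emission_tables()[s]
            for c, tab in enumerate(tables):
                f = np.bincount(stream[:, c], minlength=len(tab)) / n
                assert 0.5 * np.abs(f - tab).sum() < 0.05


class TestVideo:
    def test_mean_intensity_monotone_without_noise(self):
        cfg = small_config(noise_scale=0.0, blob_amplitude=0.0)
        labels = sample_activity_sequence(cfg, cfg.trajectory_rng(0))
        video = render_video(labels, {}, cfg, cfg.trajectory_rng(0))
        means = video.mean(axis=(1, 2))
        assert np.all(np.diff(means) > -1e-12)

    def test_blob_appears_at_diagnosis_end(self):
        cfg = small_config()
        t = generate_trajectory(cfg, 0)
        de = t.event_times["diagnosis_end"]
        b = max(2, cfg.video_size // 3)
        region = np.s_[1 : 1 + b, 1 : 1 + b]
        jump = t.video[de][region].mean() - t.video[de - 1][region].mean()
        assert jump >= cfg.blob_amplitude - 5 * cfg.noise_scale

    def test_pixels_clipped_to_unit_interval(self):
        t = generate_trajectory(small_config(), 1)
        assert t.video.min() >= 0.0 and t.video.max() <= 1.0

    def test_tiny_video_size_rejected(self):
        with pytest.raises(ConfigError):
            cfg = small_config(video_size=4)
            labels = sample_activity_sequence(cfg, cfg.trajectory_rng(0))
            render_video(labels, {}, cfg, cfg.trajectory_rng(0))


class TestDataset:
    def test_alignment_and_event_consistency(self, toy_cohort):
        cfg, trajectories = toy_cohort
        for t in trajectories:
            assert len(t.activities) == len(t.sensors) == len(t.video)
            recomputed = planted_event_times(t.activities, cfg.state_space)
            assert recomputed.get("diagnosis_end") == t.event_times.get("diagnosis_end")
            diag = cfg.state_space.index("diagnosis")
            assert t.activities[t.event_times["diagnosis_end"]] != diag

    def test_same_seed_is_byte_identical(self):
        t1 = generate_trajectory(small_config(), 2)
        t2 = generate_trajectory(small_config(), 2)
        for a, b in [(t1.activities, t2.activities), (t1.sensors, t2.sensors), (t1.video, t2.video)]:
            assert hashlib.sha256(a.tobytes()).hexdigest() == hashlib.sha256(b.tobytes()).hexdigest()

    def test_zero_trajectories(self):
        trajs, manifest = generate_dataset(small_config(n_trajectories=0))
        assert trajs == [] and manifest["trajectories"] == []

    def test_mean_length_matches_expectation(self):
        cfg = GeneratorConfig(n_trajectories=200, seed=21)
        trajs, _ = generate_dataset(cfg)
        taus = np.array([t.total_length for t in trajs])
        se = taus.std(ddof=1) / np.sqrt(taus.size)
        assert abs(taus.mean() - cfg.expected_length()) < 3 * se

    def test_manifest_regeneration(self, tmp_path):
        cfg = small_config()
        _, manifest = generate_dataset(cfg, tmp_path / "d1")
        cfg2 = GeneratorConfig.from_json(manifest["config"])
        _, manifest2 = generate_dataset(cfg2, tmp_path / "d2")
        assert manifest == manifest2
        f1 = sorted((tmp_path / "d1").glob("*"))
        f2 = sorted((tmp_path / "d2").glob("*"))
        for a, b in zip(f1, f2):
            assert a.read_bytes() == b.read_bytes()

    def test_output_collision_requires_overwrite(self, tmp_path):
        out = tmp_path / "d"
        generate_dataset(small_config(), out)
        with pytest.raises(FileExistsError):
            generate_dataset(small_config(), out)
        generate_dataset(small_config(), out, overwrite=True)


def test_default_duration_means_are_nb_means():
    cfg = small_config()
    for s, (r, p) in cfg.duration_params.items():
        mean = 1 + nbinom.mean(r, p)
        draws = 1 + nbinom.rvs(r, p, size=20_000, random_state=3)
        assert abs(draws.mean() - mean) < 3 * draws.std(ddof=1) / np.sqrt(draws.size)
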