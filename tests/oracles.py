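"""Independent brute-force oracles used by the unit and acceptance tests.

These deliberately avoid the package's dynamic programs: segmentations are
enumerated exhaustively and scored term by term, and change-point problems
are solved by unpruned optimal-partitioning recursion, so agreement with
the fast implementations is a meaningful check.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.special import logsumexp


def enumerate_segmentations(tau: int, n_states: int, d_max: int):
    """All (state, duration) run lists covering tau frames, no repeats."""

    def compositions(total):
        if total == 0:
            yield ()
            return
        for d in range(1, min(d_max, total) + 1):
            for rest in compositions(total - d):
                yield (d,) + rest

    for durs in compositions(tau):
        for states in itertools.product(range(n_states), repeat=len(durs)):
            if any(states[i] == states[i + 1] for i in range(len(states) - 1)):
                continue
            yield list(zip(states, durs))


def score_segmentation(runs, logpi, logA, logD, logDfin, logB):
    """Joint log probability of one segmentation of the observations."""
    score = logpi[runs[0][0]]
    t = 0
    for k, (s, d) in enumerate(runs):
        dur_term = logDfin if k == len(runs) - 1 else logD
        score += dur_term[s, d - 1] + logB[t : t + d, s].sum()
        if k > 0:
            score += logA[runs[k - 1][0], s]
        t += d
    return score


def brute_force_decode(model, obs):
    """(best runs, best logp, forward logp) by exhaustive enumeration."""
    obs = np.atleast_2d(np.asarray(obs))
    tau = obs.shape[0]
    pi = np.asarray(model.startprob, dtype=float)
    A = np.asarray(model.transmat, dtype=float)
    with np.errstate(divide="ignore"):
        logpi = np.log(pi)
        logA = np.log(A)
    logD = model.log_duration_matrix(tau)
    logDfin = model._final_log_duration(tau)
    logB = model._frame_logprobs(obs).T  # (tau, S)
    S = len(model.states)
    d_max = logD.shape[1]
    best, best_score, total = None, -np.inf, []
    for runs in enumerate_segmentations(tau, S, d_max):
        sc = score_segmentation(runs, logpi, logA, logD, logDfin, logB)
        total.append(sc)
        if sc > best_score + 1e-12:
            best, best_score = runs, sc
    return best, best_score, float(logsumexp(total))


def optimal_partitioning(trace, penalty, cost_fn, min_segment=1):
    """Unpruned penalized optimal-partitioning DP (change-point oracle)."""
    T = np.asarray(trace).shape[0]
    F = np.full(T + 1, np.inf)
    F[0] = -penalty
    prev = np.zeros(T + 1, dtype=int)
    for t in range(min_segment, T + 1):
        for s in range(0, t - min_segment + 1):
            if not np.isfinite(F[s]) or (s > 0 and t - s < min_segment):
                continue
            if s > 0 and s < min_segment:
                continue
            val = F[s] + cost_fn(s, t) + penalty
            if val < F[t]:
                F[t], prev[t] = val, s
    cps = []
    t = T
    while t > 0:
        s = prev[t]
        if s > 0:
            cps.append(int(s))
        t = s
    return sorted(cps), float(F[T])


def random_hsmm(rng, n_states=None, n_channels=None, d_max=None):
    """A random small explicit-duration HSMM for oracle sweeps."""
    from surgact import ExplicitDurationHSMM

    S = n_states or rng.integers(1, 4)
    C = n_channels or rng.integers(1, 3)
    dm = d_max or rng.integers(2, 5)
    pi = rng.dirichlet(np.ones(S))
    A = np.zeros((S, S))
    if S > 1:
        for i in range(S):
            row = rng.dirichlet(np.ones(S - 1))
            A[i, [j for j in range(S) if j != i]] = row
    dur = [(float(rng.uniform(0.5, 3.0)), float(rng.uniform(0.2, 0.8))) for _ in range(S)]
    emissions = []
    for s in range(S):
        chans = []
        for c in range(C):
            K = rng.integers(2, 4)
            chans.append(rng.dirichlet(np.ones(K)))
        emissions.append(chans)
    # all states must share channel symbol counts
    K_per_chan = [len(emissions[0][c]) for c in range(C)]
    for s in range(S):
        for c in range(C):
            if len(emissions[s][c]) != K_per_chan[c]:
                emissions[s][c] = rng.dirichlet(np.ones(K_per_chan[c]))
    return ExplicitDurationHSMM(
        states=tuple(f"s{i}" for i in range(S)),
        startprob=pi,
        transmat=A,
        duration_params=dur,
        d_max=int(dm),
        emissions=emissions,
    )
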