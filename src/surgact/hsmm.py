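"""Explicit-duration hidden semi-Markov model over surgical activities.

The model describes a trajectory as a sequence of activity segments: the
hidden state s_t is the current activity, dwell times are governed by an
explicit per-state duration distribution (a shifted negative binomial, to
accommodate the large between-trial variance of activity durations), and the
per-frame observation o_t is a vector of categorical sensor channels that are
conditionally independent given the state.  Self-transitions are excluded:
leaving a state is decided solely by the duration model, and the categorical
transition matrix has a zero diagonal.

Inference is exact and in log space: an explicit-duration Viterbi dynamic
program finds the single most probable segmentation, and the corresponding
forward recursion (log-sum-exp over segmentations) gives the marginal
likelihood.  Both treat the final segment with its full (renormalized)
duration pmf rather than a survival term, so the sampler, the forward pass
and Viterbi share one consistent convention; a right-censored final-segment
convention is available via ``final_censoring="survival"``.

Only the emission tables are estimated from data (maximum a posteriori with
a conjugate Dirichlet prior, from a single annotated sequence); the initial
distribution, transition matrix and duration parameters are supplied by the
user, mirroring manual initialization by a domain expert.
"""

from __future__ import annotations

import json
from typing import Sequence

import numpy as np
from scipy.special import logsumexp
from scipy.stats import nbinom
from sklearn.base import BaseEstimator

from .states import ActivityStateSpace, Segmentation

_LOGEPS = -1e8  # finite stand-in for log(0); keeps -inf out of the DP arithmetic


class DecodingError(ValueError):
    """An observation cannot be explained by any state."""


def shifted_nbinom_pmf(d, r: float, p: float) -> np.ndarray:
    """Untruncated pmf of the duration model on support d >= 1.

    The duration is 1 + NB(r, p): an activity occupies at least one frame,
    and the negative-binomial part counts the extra frames (number of
    failures before the r-th success, success probability p).
    """
    d = np.asarray(d)
    if np.any(d < 1):
        raise ValueError("durations live on d >= 1")
    return nbinom.pmf(d - 1, r, p)


def default_d_max(duration_params: Sequence[tuple[float, float]], mass: float = 0.999) -> int:
    """Smallest d covering `mass` of every state's untruncated duration pmf."""
    bound = 1
    for r, p in duration_params:
        bound = max(bound, int(nbinom.ppf(mass, r, p)) + 1)
    return bound


class ExplicitDurationHSMM(BaseEstimator):
    """Explicit-duration HSMM with negative-binomial dwell times.

    Parameters
    ----------
    states : sequence of str
        Activity names, fixing the state order.
    startprob : array (S,)
        Initial state distribution pi.
    transmat : array (S, S)
        Row-stochastic transition matrix with zero diagonal.
    duration_params : sequence of (r, p)
        Per-state negative-binomial parameters; dwell time is 1 + NB(r, p).
    d_max : int or None
        Truncation bound of the duration model.  None selects the smallest
        bound covering 99.9% of every state's duration mass (capped at the
        observation length when decoding).
    emissions : per-state, per-channel categorical tables, or None
        If None, tables must be estimated with :meth:`fit`.
    alpha : float or sequence
        Dirichlet concentration used by :meth:`fit` (per symbol; scalar is
        broadcast).  Must be >= 1 so the posterior mode exists.
    final_censoring : {"full", "survival"}
        Scoring of the last segment: its full duration pmf (default) or the
        survival function P(D >= observed remainder).
    unseen_smoothing : float or None
        If set, this probability mass is mixed uniformly into every emission
        row at inference time so unseen symbols do not abort decoding.
    """

    def __init__(
        self,
        states: Sequence[str] = ActivityStateSpace().states,
        startprob=None,
        transmat=None,
        duration_params=None,
        d_max: int | None = None,
        emissions=None,
        alpha=2.0,
        final_censoring: str = "full",
        unseen_smoothing: float | None = None,
    ):
        self.states = tuple(states)
        self.startprob = startprob
        self.transmat = transmat
        self.duration_params = duration_params
        self.d_max = d_max
        self.emissions = emissions
        self.alpha = alpha
        self.final_censoring = final_censoring
        self.unseen_smoothing = unseen_smoothing

    # -- validation --------------------------------------------------------

    @property
    def n_states(self) -> int:
        return len(self.states)

    def _validated(self):
        S = self.n_states
        pi = np.asarray(self.startprob, dtype=float)
        A = np.asarray(self.transmat, dtype=float)
        if pi.shape != (S,) or not np.isclose(pi.sum(), 1.0, atol=1e-8):
            raise ValueError("startprob must be a length-S probability vector")
        if A.shape != (S, S):
            raise ValueError("transmat must be S x S")
        if np.any(np.abs(np.diag(A)) > 0):
            raise ValueError("transmat must have a zero diagonal (no self-transitions)")
        if S > 1:
            rowsum = A.sum(axis=1)
            # all-zero rows mark terminal states (no outgoing transitions)
            if not np.all(np.isclose(rowsum, 1.0, atol=1e-8) | np.isclose(rowsum, 0.0)):
                raise ValueError("transmat rows must sum to 1 (or 0 for terminal states)")
        dur = [(float(r), float(p)) for r, p in self.duration_params]
        for r, p in dur:
            if r <= 0 or not (0 < p < 1):
                raise ValueError(f"invalid duration parameters (r={r}, p={p})")
        if len(dur) != S:
            raise ValueError("need one (r, p) pair per state")
        return pi, A, dur

    def _emission_tables(self):
        B = getattr(self, "emissions_", None)
        if B is None:
            B = self.emissions
        if B is None:
            raise ValueError("emission tables unset: pass emissions= or call fit()")
        tables = []
        for c in range(len(B[0])):
            tab = np.asarray([np.asarray(B[s][c], dtype=float) for s in range(self.n_states)])
            if not np.allclose(tab.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError(f"emission rows of channel {c} must sum to 1")
            if self.unseen_smoothing:
                eps = float(self.unseen_smoothing)
                tab = (1.0 - eps) * tab + eps / tab.shape[1]
            tables.append(tab)
        return tables  # list over channels of (S, K_c)

    def _effective_d_max(self, tau: int) -> int:
        _, _, dur = self._validated()
        if self.d_max is not None:
            if self.d_max < 1:
                raise ValueError("d_max must be >= 1")
            return int(self.d_max)
        # automatic bound: 99.9% duration mass, capped at the sequence length
        d = default_d_max(dur)
        return int(min(d, tau)) if tau >= 1 else int(d)

    def log_duration_matrix(self, tau: int) -> np.ndarray:
        """(S, d_max) log pmf of durations 1..d_max, renormalized per state."""
        _, _, dur = self._validated()
        dm = self._effective_d_max(tau)
        ds = np.arange(1, dm + 1)
        pmf = np.array([shifted_nbinom_pmf(ds, r, p) for r, p in dur])
        tot = pmf.sum(axis=1, keepdims=True)
        if np.any(tot <= 0):
            raise ValueError("duration pmf vanishes on 1..d_max; increase d_max")
        pmf = pmf / tot
        with np.errstate(divide="ignore"):
            return np.log(pmf)

    def duration_pmf(self, state: int | str, d: int, tau: int | None = None) -> float:
        """Truncated, renormalized duration pmf P(D = d | state)."""
        s = self.states.index(state) if isinstance(state, str) else int(state)
        tau = tau if tau is not None else self._effective_d_max(0)
        dm = self._effective_d_max(tau)
        if not 1 <= d <= dm:
            raise ValueError(f"duration {d} outside modeled range 1..{dm}")
        return float(np.exp(self.log_duration_matrix(tau)[s, d - 1]))

    # -- fitting (MAP emission initialization) -----------------------------

    def fit(self, labels, sensors, n_symbols: Sequence[int] | None = None):
        """Estimate emission tables by Dirichlet-MAP from one annotated sequence.

        Per state s, channel c, symbol v:
        B[s, c, v] = (n_scv + alpha_v - 1) / (N_sc + sum(alpha) - K_c),
        the mode of the Dirichlet posterior over the channel's categorical
        distribution.  alpha must be >= 1 everywhere; a state absent from the
        annotation additionally requires alpha > 1 somewhere (otherwise the
        mode is undefined).
        """
        self._validated()
        labels = np.asarray(labels, dtype=np.int64)
        sensors = np.atleast_2d(np.asarray(sensors, dtype=np.int64))
        if sensors.shape[0] != labels.shape[0]:
            raise ValueError("labels and sensors must be frame-aligned")
        n_chan = sensors.shape[1]
        if n_symbols is None:
            n_symbols = [int(sensors[:, c].max()) + 1 for c in range(n_chan)]
        self.emissions_ = map_init_emissions(
            labels, sensors, self.alpha, self.n_states, n_symbols
        )
        return self

    # -- inference ---------------------------------------------------------

    def _frame_logprobs(self, obs: np.ndarray) -> np.ndarray:
        """(S, tau) per-frame log emission probabilities, summed over channels."""
        obs = np.atleast_2d(np.asarray(obs, dtype=np.int64))
        tables = self._emission_tables()
        if obs.shape[1] != len(tables):
            raise ValueError(
                f"observation has {obs.shape[1]} channels, model has {len(tables)}"
            )
        S, tau = self.n_states, obs.shape[0]
        logB = np.zeros((S, tau))
        for c, tab in enumerate(tables):
            vals = obs[:, c]
            if vals.min() < 0 or vals.max() >= tab.shape[1]:
                bad = int(np.flatnonzero((vals < 0) | (vals >= tab.shape[1]))[0])
                raise DecodingError(
                    f"symbol {vals[bad]} at frame {bad}, channel {c} is outside "
                    f"the emission table support (size {tab.shape[1]})"
                )
            probs = tab[:, vals]  # (S, tau)
            dead = np.flatnonzero(probs.max(axis=0) <= 0)
            if dead.size:
                raise DecodingError(
                    f"symbol {vals[dead[0]]} at frame {int(dead[0])}, channel {c} "
                    "has zero probability under every state"
                )
            with np.errstate(divide="ignore"):
                logB += np.maximum(np.log(probs), _LOGEPS)
        return logB

    def _final_log_duration(self, tau: int) -> np.ndarray:
        """(S, d_max) log score of a *final* segment of each duration."""
        logD = self.log_duration_matrix(tau)
        if self.final_censoring == "full":
            return logD
        if self.final_censoring == "survival":
            # log P(D >= d) under the truncated pmf
            pmf = np.exp(logD)
            surv = np.clip(pmf[:, ::-1].cumsum(axis=1)[:, ::-1], 1e-300, None)
            return np.log(surv)
        raise ValueError("final_censoring must be 'full' or 'survival'")

    def _dp(self, obs: np.ndarray, mode: str):
        """Shared explicit-duration DP. mode='max' (Viterbi) or 'sum' (forward)."""
        obs = np.atleast_2d(np.asarray(obs, dtype=np.int64))
        tau = obs.shape[0]
        if tau == 0:
            raise ValueError("cannot decode an empty observation sequence")
        pi, A, _ = self._validated()
        S = self.n_states
        logB = self._frame_logprobs(obs)
        C = np.concatenate([np.zeros((S, 1)), np.cumsum(logB, axis=1)], axis=1)
        logD = self.log_duration_matrix(tau)
        logDfin = self._final_log_duration(tau)
        dm = logD.shape[1]
        with np.errstate(divide="ignore"):
            logpi = np.where(pi > 0, np.log(np.clip(pi, 1e-300, None)), _LOGEPS)
            logA = np.where(A > 0, np.log(np.clip(A, 1e-300, None)), _LOGEPS)

        # delta[t, s]: best (or total) log prob of frames [0, t) with the last
        # segment ending at t in state s.  prev_in[t, s]: score of the best
        # (or total) way to *enter* state s at time t.
        delta = np.full((tau + 1, S), _LOGEPS)
        prev_in = np.full((tau + 1, S), _LOGEPS)
        prev_in[0] = logpi
        bp_dur = np.zeros((tau + 1, S), dtype=np.int64)
        bp_src = np.full((tau + 1, S), -1, dtype=np.int64)

        for t in range(1, tau + 1):
            dmax_t = min(dm, t)
            ds = np.arange(1, dmax_t + 1)
            starts = t - ds  # (D,)
            useD = logDfin if t == tau else logD
            # cand[d-1, s] = prev_in[t-d, s] + logD[s, d] + sum of emissions
            cand = (
                prev_in[starts, :]
                + useD[:, :dmax_t].T
                + (C[:, t][None, :] - C[:, starts].T)
            )
            if mode == "max":
                best = np.argmax(cand, axis=0)  # first occurrence -> shortest d
                delta[t] = cand[best, np.arange(S)]
                bp_dur[t] = ds[best]
            else:
                delta[t] = logsumexp(cand, axis=0)
            if mode == "max":
                # entering state s at time t from the best predecessor
                scores = delta[t][:, None] + logA  # (S_from, S_to)
                bp = np.argmax(scores, axis=0)  # lowest index wins ties
                prev_in[t] = scores[bp, np.arange(S)]
                bp_src[t] = bp
            else:
                prev_in[t] = logsumexp(delta[t][:, None] + logA, axis=0)

        if mode == "sum":
            return float(logsumexp(delta[tau]))

        # backtrack
        s = int(np.argmax(delta[tau]))
        logp = float(delta[tau, s])
        if logp <= _LOGEPS / 2:
            raise DecodingError("no segmentation has positive probability")
        t = tau
        segments: list[tuple[int, int, int]] = []
        while t > 0:
            d = int(bp_dur[t, s])
            segments.append((s, t - d, t))
            t -= d
            if t > 0:
                s = int(bp_src[t, s])
        segments.reverse()
        return Segmentation(segments), logp

    def decode(self, obs) -> tuple[Segmentation, float]:
        """Most probable segmentation (explicit-duration Viterbi) and its log prob."""
        return self._dp(obs, "max")

    def predict(self, obs) -> np.ndarray:
        """Per-frame activity indices of the Viterbi segmentation."""
        seg, _ = self.decode(obs)
        return seg.to_labels()

    def score(self, obs) -> float:
        """Marginal log P(obs): forward algorithm, log-sum-exp over segmentations."""
        return self._dp(obs, "sum")

    # -- sampling ----------------------------------------------------------

    def sample(self, max_frames: int, random_state=None) -> tuple[Segmentation, np.ndarray]:
        """Generative draw, truncated at max_frames frames."""
        if max_frames < 1:
            raise ValueError("max_frames must be >= 1")
        pi, A, _ = self._validated()
        tables = self._emission_tables()
        rng = np.random.default_rng(random_state)
        logD = self.log_duration_matrix(max_frames)
        dur_pmfs = np.exp(logD)
        labels = np.empty(max_frames, dtype=np.int64)
        t = 0
        s = int(rng.choice(self.n_states, p=pi))
        while t < max_frames:
            d = 1 + int(rng.choice(dur_pmfs.shape[1], p=dur_pmfs[s]))
            d = min(d, max_frames - t)
            labels[t : t + d] = s
            t += d
            if t < max_frames:
                nxt = A[s]
                if nxt.sum() <= 0:  # terminal state: extend to the bound
                    labels[t:] = s
                    break
                s = int(rng.choice(self.n_states, p=nxt))
        obs = np.empty((max_frames, len(tables)), dtype=np.int64)
        for c, tab in enumerate(tables):
            cum = tab.cumsum(axis=1)
            u = rng.random(max_frames)
            obs[:, c] = (u[:, None] > cum[labels]).sum(axis=1)
        return Segmentation.from_labels(labels), obs

    # -- serialization -----------------------------------------------------

    def to_json(self, path=None):
        B = getattr(self, "emissions_", None) or self.emissions
        spec = {
            "states": list(self.states),
            "startprob": np.asarray(self.startprob, dtype=float).tolist(),
            "transmat": np.asarray(self.transmat, dtype=float).tolist(),
            "duration_params": [[float(r), float(p)] for r, p in self.duration_params],
            "d_max": self.d_max,
            "emissions": None
            if B is None
            else [[np.asarray(t, dtype=float).tolist() for t in chan] for chan in B],
            "final_censoring": self.final_censoring,
        }
        text = json.dumps(spec, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "ExplicitDurationHSMM":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            spec = json.loads(source)
        else:
            with open(source) as fh:
                spec = json.load(fh)
        return cls(
            states=spec["states"],
            startprob=spec["startprob"],
            transmat=spec["transmat"],
            duration_params=[tuple(x) for x in spec["duration_params"]],
            d_max=spec["d_max"],
            emissions=spec["emissions"],
            final_censoring=spec.get("final_censoring", "full"),
        )


def map_init_emissions(labels, sensors, alpha, n_states: int, n_symbols: Sequence[int]):
    """Dirichlet-MAP categorical emission tables from an annotated sequence.

    Returns nested lists: tables[state][channel] is a probability vector over
    that channel's symbols.  With a uniform prior (alpha = 1 everywhere) the
    estimate reduces to empirical per-state symbol frequencies.
    """
    labels = np.asarray(labels, dtype=np.int64)
    sensors = np.atleast_2d(np.asarray(sensors, dtype=np.int64))
    if sensors.shape[0] != labels.shape[0]:
        raise ValueError("labels and sensors must be frame-aligned")
    n_chan = sensors.shape[1]
    tables: list[list[np.ndarray]] = []
    for s in range(n_states):
        mask = labels == s
        per_chan = []
        for c in range(n_chan):
            K = int(n_symbols[c])
            a = np.broadcast_to(np.asarray(alpha, dtype=float), (K,)).copy()
            if np.any(a < 1):
                raise ValueError("alpha entries must be >= 1 (MAP mode undefined)")
            counts = np.bincount(sensors[mask, c], minlength=K).astype(float)
            denom = counts.sum() + a.sum() - K
            if denom <= 0:
                raise ValueError(
                    f"state {s} has no annotated frames and the prior is not "
                    "strictly regularizing (need some alpha > 1)"
                )
            per_chan.append((counts + a - 1.0) / denom)
        tables.append(per_chan)
    return tables


# -- thin functional wrappers (spec-style operation names) -----------------


def duration_pmf(model: ExplicitDurationHSMM, state, d: int, tau: int | None = None) -> float:
    return model.duration_pmf(state, d, tau)


def viterbi_decode(model: ExplicitDurationHSMM, obs) -> tuple[Segmentation, float]:
    return model.decode(obs)


def sequence_loglik(model: ExplicitDurationHSMM, obs) -> float:
    return model.score(obs)


def sample(model: ExplicitDurationHSMM, max_frames: int, random_state=None):
    return model.sample(max_frames, random_state)
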