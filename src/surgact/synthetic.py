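"""Synthetic hysteroscopy-simulator trajectories for end-to-end testing.

Real simulator recordings of hysteroscopic myomectomy trials are rarely
shareable, so this module generates structurally matched stand-ins: activity
sequences drawn from a task graph with negative-binomial dwell times,
activity-conditional categorical sensor channels (with deliberate emission
ambiguity between selected activity pairs, mimicking activities whose tool
usage is indistinguishable from the sensors alone), and a toy grayscale
video whose global intensity drifts with surgery progress and which shows a
bright "tool" blob from the end of the diagnosis activity onward — the
visual cue that the hysteroscope has appeared in the camera picture.

Every quantity in a trajectory is derived from a per-trajectory random
stream spawned from the master seed by a counter, so datasets regenerate
bit-identically from their manifest.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .states import (
    ActivityStateSpace,
    Segmentation,
    labels_to_csv,
    sensors_to_csv,
)


class ConfigError(ValueError):
    """Invalid generator configuration."""


class GenerationError(RuntimeError):
    """Sampling reached a state from which it cannot proceed."""


def _default_graph() -> dict[str, list[str]]:
    return {
        "diagnosis": ["position hysteroscope"],
        "position hysteroscope": ["cutting"],
        "cutting": ["position hysteroscope", "coagulation", "clear view", "handle chips"],
        "coagulation": ["position hysteroscope", "cutting", "clear view", "handle chips"],
        "clear view": ["position hysteroscope", "cutting", "coagulation", "handle chips"],
        "handle chips": [],
    }


def _default_durations() -> dict[str, tuple[float, float]]:
    # (r, p) of the shifted negative binomial; mean dwell = 1 + r(1-p)/p
    return {
        "diagnosis": (22.0, 2.0 / 3.0),  # mean 12 frames (6 s at 2 fps)
        "position hysteroscope": (3.0, 0.5),  # mean 4
        "cutting": (5.0, 0.5),  # mean 6
        "coagulation": (3.0, 0.5),  # mean 4
        "clear view": (3.0, 0.5),  # mean 4
        "handle chips": (6.0, 0.5),  # mean 7
    }


#: symbols per default sensor channel (pedal, valve, pedal, coarse position)
DEFAULT_CHANNEL_SIZES = (3, 2, 4, 3)


def _default_sensor_spec(states, channel_sizes=DEFAULT_CHANNEL_SIZES, sharpness=0.7):
    """Each activity prefers one symbol per channel w.p. `sharpness`."""
    spec = {}
    for i, s in enumerate(states):
        chans = []
        for K in channel_sizes:
            tab = np.full(K, (1.0 - sharpness) / (K - 1)) if K > 1 else np.ones(1)
            if K > 1:
                tab[i % K] = sharpness
            chans.append(tab)
        spec[s] = chans
    return spec


@dataclass
class GeneratorConfig:
    """Study conditions of the synthetic cohort.

    Defaults emulate a realistic acquisition setting at desk scale: 38 trials,
    six activities starting with diagnosis and ending with handle chips,
    2 fps frames, 16x16 grayscale video, four categorical sensor channels,
    and sensor ambiguity between (diagnosis, position hysteroscope) and
    (position hysteroscope, handle chips) — the activity pairs whose sensor
    signatures the study reports as hard to separate.
    """

    n_trajectories: int = 38
    frame_rate: float = 2.0
    state_space: ActivityStateSpace = field(default_factory=ActivityStateSpace)
    activity_graph: dict = field(default_factory=_default_graph)
    initial_distribution: dict = field(default_factory=lambda: {"diagnosis": 1.0})
    duration_params: dict = field(default_factory=_default_durations)
    sensor_spec: dict | None = None
    ambiguity_pairs: list = field(
        default_factory=lambda: [
            ("diagnosis", "position hysteroscope"),
            ("position hysteroscope", "handle chips"),
        ]
    )
    final_activity: str | None = "handle chips"
    video_size: int = 16
    blob_amplitude: float = 0.6
    noise_scale: float = 0.02
    drift_range: tuple[float, float] = (0.15, 0.55)
    gain_jitter: float = 0.25
    offset_jitter: float = 0.08
    max_frames: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sensor_spec is None:
            self.sensor_spec = _default_sensor_spec(self.state_space.states)
        self.sensor_spec = {
            s: [np.asarray(t, dtype=float) for t in chans]
            for s, chans in self.sensor_spec.items()
        }
        for a, b in self.ambiguity_pairs:
            self.sensor_spec[b] = [t.copy() for t in self.sensor_spec[a]]
        self.validate()

    def validate(self) -> None:
        names = self.state_space.states
        pi = self.initial_vector()
        if abs(pi.sum() - 1.0) > 1e-12:
            raise ConfigError("initial_distribution must sum to 1")
        if np.any(pi < 0):
            raise ConfigError("initial_distribution has negative mass")
        for s, succ in self.activity_graph.items():
            if s in succ:
                raise ConfigError(f"activity graph has a self-loop at {s!r}")
        for s in names:
            if s not in self.duration_params:
                raise ConfigError(f"missing duration parameters for {s!r}")
            r, p = self.duration_params[s]
            if r <= 0 or not (0 < p < 1):
                raise ConfigError(f"invalid duration parameters for {s!r}")
            if s not in self.sensor_spec:
                raise ConfigError(f"missing sensor distributions for {s!r}")
            for c, tab in enumerate(self.sensor_spec[s]):
                if abs(tab.sum() - 1.0) > 1e-12 or np.any(tab < 0):
                    raise ConfigError(f"sensor table of {s!r} channel {c} is not a distribution")
        for a, b in self.ambiguity_pairs:
            for ta, tb in zip(self.sensor_spec[a], self.sensor_spec[b]):
                if not np.array_equal(ta, tb):
                    raise ConfigError(f"ambiguity pair ({a!r}, {b!r}) tables differ")

    # -- derived views -----------------------------------------------------

    def initial_vector(self) -> np.ndarray:
        pi = np.zeros(len(self.state_space))
        for name, w in self.initial_distribution.items():
            pi[self.state_space.index(name)] = w
        return pi

    def transition_matrix(self) -> np.ndarray:
        """Uniform transition probabilities over the allowed graph edges."""
        n = len(self.state_space)
        A = np.zeros((n, n))
        for s, succ in self.activity_graph.items():
            i = self.state_space.index(s)
            for t in succ:
                A[i, self.state_space.index(t)] = 1.0 / len(succ)
        return A

    def duration_array(self) -> list[tuple[float, float]]:
        return [tuple(self.duration_params[s]) for s in self.state_space.states]

    def emission_tables(self):
        """Per-state per-channel tables in state order (true generator tables)."""
        return [[t.copy() for t in self.sensor_spec[s]] for s in self.state_space.states]

    def channel_sizes(self) -> tuple[int, ...]:
        first = self.sensor_spec[self.state_space.states[0]]
        return tuple(len(t) for t in first)

    def expected_length(self) -> float:
        """Expected tau (frames) from the absorbing-chain visit counts."""
        names = self.state_space.states
        means = np.array([1.0 + r * (1 - p) / p for r, p in self.duration_array()])
        if self.final_activity is None:
            raise ConfigError("expected_length requires a final (absorbing) activity")
        f = self.state_space.index(self.final_activity)
        trans = [i for i in range(len(names)) if i != f]
        A = self.transition_matrix()
        Q = A[np.ix_(trans, trans)]
        pi = self.initial_vector()
        visits = np.linalg.solve(np.eye(len(trans)) - Q.T, pi[trans])
        reach_final = pi[f] + visits @ A[np.ix_(trans, [f])].ravel()
        return float(visits @ means[trans] + reach_final * means[f])

    def trajectory_rng(self, index: int) -> np.random.Generator:
        """Per-trajectory stream: master seed + trajectory counter."""
        return np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=(index,)))

    def to_json(self) -> dict:
        cfg = {
            "n_trajectories": self.n_trajectories,
            "frame_rate": self.frame_rate,
            "states": list(self.state_space.states),
            "activity_graph": self.activity_graph,
            "initial_distribution": self.initial_distribution,
            "duration_params": {k: list(v) for k, v in self.duration_params.items()},
            "sensor_spec": {k: [t.tolist() for t in v] for k, v in self.sensor_spec.items()},
            "ambiguity_pairs": [list(p) for p in self.ambiguity_pairs],
            "final_activity": self.final_activity,
            "video_size": self.video_size,
            "blob_amplitude": self.blob_amplitude,
            "noise_scale": self.noise_scale,
            "drift_range": list(self.drift_range),
            "gain_jitter": self.gain_jitter,
            "offset_jitter": self.offset_jitter,
            "max_frames": self.max_frames,
            "seed": self.seed,
        }
        return cfg

    @classmethod
    def from_json(cls, cfg: dict) -> "GeneratorConfig":
        cfg = copy.deepcopy(cfg)
        states = cfg.pop("states", None)
        kwargs = dict(cfg)
        if states is not None:
            kwargs["state_space"] = ActivityStateSpace(tuple(states))
        if kwargs.get("drift_range") is not None:
            kwargs["drift_range"] = tuple(kwargs["drift_range"])
        if kwargs.get("ambiguity_pairs") is not None:
            kwargs["ambiguity_pairs"] = [tuple(p) for p in kwargs["ambiguity_pairs"]]
        if kwargs.get("duration_params") is not None:
            kwargs["duration_params"] = {k: tuple(v) for k, v in kwargs["duration_params"].items()}
        return cls(**kwargs)


@dataclass
class SyntheticTrajectory:
    """One simulated trial: labels, sensors, video and planted event times."""

    activities: np.ndarray  # (tau,) activity indices
    sensors: np.ndarray  # (tau, n_channels) categorical codes
    video: np.ndarray  # (tau, H, W) in [0, 1]
    event_times: dict
    seed: list
    index: int = 0

    @property
    def total_length(self) -> int:
        return int(self.activities.shape[0])

    def segmentation(self) -> Segmentation:
        return Segmentation.from_labels(self.activities)


# -- sampling operations ---------------------------------------------------


def sample_activity_sequence(config: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-frame activity indices from the task graph and duration models."""
    space = config.state_space
    pi = config.initial_vector()
    current = space.name(int(rng.choice(len(space), p=pi)))
    runs: list[tuple[int, int]] = []
    total = 0
    while True:
        r, p = config.duration_params[current]
        d = 1 + int(rng.negative_binomial(r, p))
        d = min(d, config.max_frames - total)
        runs.append((space.index(current), d))
        total += d
        if current == config.final_activity or total >= config.max_frames:
            break
        succ = config.activity_graph.get(current, [])
        if not succ:
            raise GenerationError(
                f"activity {current!r} has no outgoing transitions but is not "
                "the final activity"
            )
        weights = config.transition_matrix()[space.index(current)]
        nxt = int(rng.choice(len(space), p=weights))
        current = space.name(nxt)
    labels = np.concatenate([np.full(d, s, dtype=np.int64) for s, d in runs])
    return labels


def render_sensor_stream(
    activities: np.ndarray, config: GeneratorConfig, rng: np.random.Generator
) -> np.ndarray:
    """One categorical draw per frame per channel, conditioned on the activity."""
    activities = np.asarray(activities, dtype=np.int64)
    if activities.size == 0:
        raise ValueError("activity sequence is empty")
    tables = config.emission_tables()
    n_chan = len(tables[0])
    tau = activities.size
    out = np.empty((tau, n_chan), dtype=np.int64)
    for c in range(n_chan):
        tab = np.asarray([tables[s][c] for s in range(len(config.state_space))])
        cum = tab.cumsum(axis=1)
        u = rng.random(tau)
        out[:, c] = (u[:, None] > cum[activities]).sum(axis=1)
    return out


def planted_event_times(activities: np.ndarray, space: ActivityStateSpace) -> dict:
    """Event frames recomputed from the labels (diagnosis end, first cut end)."""
    activities = np.asarray(activities, dtype=np.int64)
    events: dict[str, int] = {}
    diag = space.index("diagnosis") if "diagnosis" in space.states else None
    if diag is not None and activities[0] == diag:
        nond = np.flatnonzero(activities != diag)
        if nond.size:
            events["diagnosis_end"] = int(nond[0])
    if "cutting" in space.states:
        cut = space.index("cutting")
        idx = np.flatnonzero(activities == cut)
        if idx.size:
            first = idx[0]
            after = np.flatnonzero(activities[first:] != cut)
            if after.size:
                events["first_cut_end"] = int(first + after[0])
    return events


def render_video(
    activities: np.ndarray,
    event_times: dict,
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Toy grayscale frames: progress drift + tool blob + pixel noise.

    The global intensity drifts linearly with t/tau (so remaining progress
    is decodable from single frames up to a per-trajectory gain/offset
    jitter), and a bright square "tool" blob appears at diagnosis_end and
    stays — the appearance of the hysteroscope in the camera picture.
    """
    activities = np.asarray(activities, dtype=np.int64)
    tau = activities.size
    H = config.video_size
    if H < 8:
        raise ConfigError("video_size must be >= 8 to render the tool blob")
    de = event_times.get("diagnosis_end")
    recomputed = planted_event_times(activities, config.state_space).get("diagnosis_end")
    if de is not None and recomputed is not None and de != recomputed:
        raise ValueError("event_times inconsistent with the activity sequence")
    lo, hi = config.drift_range
    progress = np.arange(1, tau + 1) / tau
    gain = 1.0 + config.gain_jitter * (2 * rng.random() - 1)
    offset = config.offset_jitter * (2 * rng.random() - 1)
    base = offset + gain * (lo + (hi - lo) * progress)
    frames = np.repeat(base[:, None, None], H, axis=1).repeat(H, axis=2)
    if de is not None:
        b = max(2, H // 3)
        frames[de:, 1 : 1 + b, 1 : 1 + b] += config.blob_amplitude
    if config.noise_scale > 0:
        frames = frames + rng.normal(0.0, config.noise_scale, frames.shape)
    return np.clip(frames, 0.0, 1.0)


def generate_trajectory(config: GeneratorConfig, index: int) -> SyntheticTrajectory:
    rng = config.trajectory_rng(index)
    labels = sample_activity_sequence(config, rng)
    sensors = render_sensor_stream(labels, config, rng)
    events = planted_event_times(labels, config.state_space)
    video = render_video(labels, events, config, rng)
    return SyntheticTrajectory(
        activities=labels,
        sensors=sensors,
        video=video,
        event_times=events,
        seed=[config.seed, index],
        index=index,
    )


def generate_dataset(
    config: GeneratorConfig,
    out_dir: str | Path | None = None,
    overwrite: bool = False,
) -> tuple[list[SyntheticTrajectory], dict]:
    """n_trajectories independent draws plus a regeneration manifest."""
    trajectories = [generate_trajectory(config, i) for i in range(config.n_trajectories)]
    manifest = {
        "config": config.to_json(),
        "trajectories": [
            {
                "index": t.index,
                "seed": t.seed,
                "tau": t.total_length,
                "event_times": t.event_times,
            }
            for t in trajectories
        ],
    }
    if out_dir is not None:
        out = Path(out_dir)
        if out.exists() and any(out.iterdir()) and not overwrite:
            raise FileExistsError(f"{out} is non-empty; pass overwrite=True")
        out.mkdir(parents=True, exist_ok=True)
        for t in trajectories:
            stem = out / f"trajectory_{t.index:03d}"
            labels_to_csv(t.activities, f"{stem}_activities.csv", config.state_space)
            sensors_to_csv(t.sensors, f"{stem}_sensors.csv")
            np.save(f"{stem}_video.npy", t.video.astype(np.float32))
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)
    return trajectories, manifest
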