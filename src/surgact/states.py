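"""Core domain types: the activity state space and temporal segmentations.

The simulated procedure is a hysteroscopic myomectomy, decomposed by a
hierarchical task model into six activities: an initial diagnostic inspection
of the uterus followed by an operative part (positioning the hysteroscope,
cutting, coagulation, clearing the view, and finally handling the resected
chips).  Per-frame activity labels and interval segmentations are the two
interchangeable views of the same object; conversions are provided here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Canonical activity order; indices everywhere refer to this order.
DEFAULT_ACTIVITIES = (
    "diagnosis",
    "position hysteroscope",
    "cutting",
    "coagulation",
    "clear view",
    "handle chips",
)


@dataclass(frozen=True)
class ActivityStateSpace:
    """Ordered, fixed set of activity names with index <-> name mapping."""

    states: tuple[str, ...] = DEFAULT_ACTIVITIES

    def __post_init__(self) -> None:
        if len(set(self.states)) != len(self.states):
            raise ValueError("activity names must be unique")
        if len(self.states) == 0:
            raise ValueError("state space must be non-empty")

    def __len__(self) -> int:
        return len(self.states)

    def index(self, name: str) -> int:
        try:
            return self.states.index(name)
        except ValueError:
            raise KeyError(f"unknown activity {name!r}; known: {list(self.states)}")

    def name(self, idx: int) -> str:
        return self.states[idx]


@dataclass
class Segmentation:
    """Contiguous labeling of [0, tau) by half-open (state, start, end) runs.

    ``intervals`` holds integer state indices; intervals are sorted,
    gap-free, non-overlapping and consecutive intervals carry different
    states (run-length canonical form).
    """

    intervals: list[tuple[int, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        prev_end = 0
        prev_state = None
        for state, start, end in self.intervals:
            if start != prev_end:
                raise ValueError(f"intervals not contiguous at frame {start}")
            if end <= start:
                raise ValueError(f"empty or inverted interval ({state},{start},{end})")
            if prev_state is not None and state == prev_state:
                raise ValueError("consecutive intervals share a state; merge them")
            prev_end = end
            prev_state = state

    @property
    def n_frames(self) -> int:
        return self.intervals[-1][2] if self.intervals else 0

    def to_labels(self) -> np.ndarray:
        """Expand to a per-frame integer label array of length tau."""
        out = np.empty(self.n_frames, dtype=np.int64)
        for state, start, end in self.intervals:
            out[start:end] = state
        return out

    @classmethod
    def from_labels(cls, labels: Sequence[int] | np.ndarray) -> "Segmentation":
        labels = np.asarray(labels, dtype=np.int64)
        if labels.ndim != 1 or labels.size == 0:
            raise ValueError("labels must be a non-empty 1-D sequence")
        change = np.flatnonzero(np.diff(labels)) + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [labels.size]])
        return cls([(int(labels[s]), int(s), int(e)) for s, e in zip(starts, ends)])

    # -- interchange -------------------------------------------------------

    def to_frame(self, space: ActivityStateSpace | None = None) -> pd.DataFrame:
        names = (lambda s: space.name(s)) if space is not None else (lambda s: s)
        return pd.DataFrame(
            [(names(s), a, b) for s, a, b in self.intervals],
            columns=["state", "start", "end"],
        )

    def to_csv(self, path, space: ActivityStateSpace | None = None) -> None:
        self.to_frame(space).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, space: ActivityStateSpace | None = None) -> "Segmentation":
        df = pd.read_csv(path)
        conv = (lambda s: space.index(s)) if space is not None else (lambda s: int(s))
        return cls([(conv(r.state), int(r.start), int(r.end)) for r in df.itertuples()])


def labels_to_csv(labels: np.ndarray, path, space: ActivityStateSpace | None = None) -> None:
    names = [space.name(int(a)) for a in labels] if space else list(map(int, labels))
    pd.DataFrame({"frame": np.arange(len(labels)), "activity": names}).to_csv(path, index=False)


def labels_from_csv(path, space: ActivityStateSpace | None = None) -> np.ndarray:
    df = pd.read_csv(path)
    if space is not None:
        return np.array([space.index(a) for a in df["activity"]], dtype=np.int64)
    return df["activity"].to_numpy(dtype=np.int64)


def sensors_to_csv(sensors: np.ndarray, path) -> None:
    """Sensor stream (tau, n_channels) of categorical codes -> CSV."""
    sensors = np.asarray(sensors)
    cols = {f"channel_{c}": sensors[:, c] for c in range(sensors.shape[1])}
    pd.DataFrame({"frame": np.arange(sensors.shape[0]), **cols}).to_csv(path, index=False)


def sensors_from_csv(path) -> np.ndarray:
    df = pd.read_csv(path)
    chans = [c for c in df.columns if c.startswith("channel_")]
    chans.sort(key=lambda c: int(c.split("_")[1]))
    return df[chans].to_numpy(dtype=np.int64)
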