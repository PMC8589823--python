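"""Segmentation quality metrics and model comparison.

Mean intersection-over-union (mIoU) per activity across trajectories,
computed on frame sets so the score is invariant to how intervals are
split, plus frame accuracy and timeline visualizations for side-by-side
model comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .states import ActivityStateSpace, Segmentation


def _labels(seg) -> np.ndarray:
    if isinstance(seg, Segmentation):
        return seg.to_labels()
    return np.asarray(seg, dtype=np.int64)


def activity_iou(pred, truth, activity: int) -> float:
    """Frame-set IoU of one activity; 1.0 when absent from both sides."""
    p, t = _labels(pred), _labels(truth)
    if p.shape[0] != t.shape[0]:
        raise ValueError(f"segmentations cover {p.shape[0]} vs {t.shape[0]} frames")
    pm, tm = p == activity, t == activity
    union = np.count_nonzero(pm | tm)
    if union == 0:
        return 1.0
    return float(np.count_nonzero(pm & tm) / union)


def frame_accuracy(pred, truth) -> float:
    p, t = _labels(pred), _labels(truth)
    if p.shape[0] != t.shape[0]:
        raise ValueError("segmentations cover different frame ranges")
    return float(np.mean(p == t))


def mean_iou(values, ddof: int = 1) -> tuple[float, float]:
    """Mean and (sample, by default) std of per-trajectory IoU values."""
    values = np.asarray(list(values), dtype=float)
    if values.size == 0:
        raise ValueError("no IoU values to aggregate")
    std = 0.0 if values.size <= ddof else float(values.std(ddof=ddof))
    return float(values.mean()), std


@dataclass
class EvalReport:
    """Per-trajectory and aggregated IoU for one model."""

    model: str
    per_trajectory: pd.DataFrame  # columns: trajectory, activity, iou
    summary: pd.DataFrame  # columns: activity, mean_iou, std_iou
    frame_accuracy: float

    def to_json(self) -> dict:
        return {
            "model": self.model,
            "frame_accuracy": self.frame_accuracy,
            "summary": self.summary.to_dict(orient="records"),
        }


def evaluate_model(
    model_name: str,
    decodings,
    truths,
    activities,
    space: ActivityStateSpace | None = None,
    skip_both_absent: bool = False,
) -> EvalReport:
    """IoU report for one model over aligned trajectory lists.

    With ``skip_both_absent`` trajectories where an activity occurs in
    neither prediction nor ground truth are excluded from that activity's
    mean instead of contributing an IoU of 1.
    """
    decodings, truths = list(decodings), list(truths)
    if len(decodings) != len(truths):
        raise ValueError("decodings and ground truths are misaligned")
    name_of = (lambda a: space.name(a)) if space is not None else (lambda a: a)
    rows = []
    accs = []
    for j, (pred, truth) in enumerate(zip(decodings, truths)):
        p, t = _labels(pred), _labels(truth)
        accs.append(frame_accuracy(p, t))
        for a in activities:
            present = np.any(p == a) or np.any(t == a)
            if skip_both_absent and not present:
                continue
            rows.append({"trajectory": j, "activity": name_of(a),
                         "iou": activity_iou(p, t, a)})
    per_traj = pd.DataFrame(rows, columns=["trajectory", "activity", "iou"])
    summary = (
        per_traj.groupby("activity")["iou"]
        .agg(mean_iou="mean", std_iou=lambda v: mean_iou(v)[1])
        .reset_index()
    )
    return EvalReport(
        model=model_name,
        per_trajectory=per_traj,
        summary=summary,
        frame_accuracy=float(np.mean(accs)),
    )


def compare_models(
    decodings: dict,
    truths,
    activities,
    space: ActivityStateSpace | None = None,
    skip_both_absent: bool = False,
) -> tuple[pd.DataFrame, dict[str, EvalReport]]:
    """Side-by-side mIoU table for several models on the same trajectories."""
    reports = {
        name: evaluate_model(name, decs, truths, activities, space, skip_both_absent)
        for name, decs in decodings.items()
    }
    rows = []
    for name, rep in reports.items():
        row = {"model": name, "frame_accuracy": rep.frame_accuracy}
        for rec in rep.summary.itertuples():
            row[f"miou:{rec.activity}"] = rec.mean_iou
            row[f"std:{rec.activity}"] = rec.std_iou
        rows.append(row)
    return pd.DataFrame(rows), reports


def plot_segmentations(
    decodings: dict,
    truths=None,
    space: ActivityStateSpace | None = None,
    path=None,
):
    """Horizontal-bar timelines of segmentations per trajectory per model."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    names = list(decodings)
    n_traj = len(next(iter(decodings.values())))
    n_rows = len(names) + (1 if truths is not None else 0)
    n_states = len(space) if space is not None else int(
        max(_labels(s).max() for segs in decodings.values() for s in segs) + 1
    )
    cmap = plt.get_cmap("tab10")
    fig, axes = plt.subplots(n_traj, 1, figsize=(8, 0.6 * n_rows * n_traj + 1),
                             squeeze=False)
    rowsets = list(decodings.items())
    if truths is not None:
        rowsets.append(("annotation", truths))
    for j in range(n_traj):
        ax = axes[j, 0]
        for k, (name, segs) in enumerate(rowsets):
            labels = _labels(segs[j])
            seg = Segmentation.from_labels(labels)
            for state, start, end in seg.intervals:
                ax.barh(k, end - start, left=start, color=cmap(state % 10), height=0.8)
        ax.set_yticks(range(len(rowsets)))
        ax.set_yticklabels([n for n, _ in rowsets], fontsize=6)
        ax.set_ylabel(f"traj {j}", fontsize=6)
    handles = [plt.Rectangle((0, 0), 1, 1, color=cmap(i % 10)) for i in range(n_states)]
    state_names = space.states if space is not None else [str(i) for i in range(n_states)]
    fig.legend(handles, state_names, loc="lower center", ncol=3, fontsize=6)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
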