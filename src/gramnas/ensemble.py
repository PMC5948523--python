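"""Majority-voting committees over trained models and confusion matrices."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import SensorFrame, slide_windows
from .trainer import TrainedModel, predict, weighted_f1

__all__ = [
    "Committee",
    "ConfusionMatrix",
    "majority_vote",
    "incremental_committee_eval",
    "confusion_matrix",
    "committee_predict",
]


@dataclass
class Committee:
    """Ordered set of trained models voting by majority on shared windows."""

    members: list[TrainedModel]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("a committee needs at least one member")

    def __len__(self) -> int:
        return len(self.members)


def majority_vote(
    per_model_labels: np.ndarray,
    per_model_probs: np.ndarray | None = None,
) -> np.ndarray:
    """Modal label per window across members.

    ``per_model_labels`` has shape (members, windows).  Ties are broken by
    the highest summed probability among the tied classes (when probabilities
    are given), then by the lowest class index.
    """
    labels = np.asarray(per_model_labels, dtype=int)
    if labels.ndim != 2:
        raise ValueError("per_model_labels must be (members, windows)")
    M, N = labels.shape
    n_classes = int(labels.max()) + 1
    if per_model_probs is not None:
        per_model_probs = np.asarray(per_model_probs, dtype=float)
        n_classes = max(n_classes, per_model_probs.shape[2])
    votes = np.zeros((N, n_classes), dtype=int)
    for m in range(M):
        np.add.at(votes, (np.arange(N), labels[m]), 1)
    out = np.empty(N, dtype=int)
    top = votes.max(axis=1)
    for i in range(N):
        tied = np.flatnonzero(votes[i] == top[i])
        if len(tied) == 1 or per_model_probs is None:
            out[i] = tied[0]
        else:
            summed = per_model_probs[:, i, tied].sum(axis=0)
            out[i] = tied[np.argmax(summed)]  # argmax keeps lowest index on ties
    return out


def _member_windows(member: TrainedModel, frame: SensorFrame, label_rule: str):
    return slide_windows(
        frame,
        member.topology.window_size,
        member.topology.window_step,
        label_rule=label_rule,
    )


def committee_predict(
    committee: Committee,
    test_windows,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-member labels/probs plus the majority-vote labels on one shared
    window set.  All members must share (w, wstep)."""
    w = committee.members[0].topology.window_size
    step = committee.members[0].topology.window_step
    for m in committee.members:
        if m.topology.window_size != w or m.topology.window_step != step:
            raise ValueError("committee members must share window size and step")
    all_labels, all_probs = [], []
    for member in committee.members:
        labels, probs = predict(member.model, test_windows.tensor)
        all_labels.append(labels)
        all_probs.append(probs)
    labels_arr = np.stack(all_labels)
    probs_arr = np.stack(all_probs)
    return labels_arr, probs_arr, majority_vote(labels_arr, probs_arr)


def incremental_committee_eval(
    models_ordered_by_fitness: list[TrainedModel],
    test_windows,
    true_labels: np.ndarray,
) -> list[dict]:
    """Evaluate committees of the first k models for k = 1..K.

    Returns one row per k: ``{"k", "committee_f1", "mean_member_f1"}``.
    """
    rows = []
    member_f1s: list[float] = []
    member_labels: list[np.ndarray] = []
    member_probs: list[np.ndarray] = []
    for k, member in enumerate(models_ordered_by_fitness, start=1):
        labels, probs = predict(member.model, test_windows.tensor)
        member_labels.append(labels)
        member_probs.append(probs)
        member_f1s.append(weighted_f1(true_labels, labels).f1)
        voted = majority_vote(np.stack(member_labels), np.stack(member_probs))
        rows.append(
            {
                "k": k,
                "committee_f1": weighted_f1(true_labels, voted).f1,
                "mean_member_f1": float(np.mean(member_f1s)),
            }
        )
    return rows


@dataclass
class ConfusionMatrix:
    counts: np.ndarray       # (n_classes, n_classes), rows = true class
    normalized: np.ndarray   # rows divided by their support; zero rows stay 0


def confusion_matrix(
    true_labels,
    predicted_labels,
    n_classes: int,
) -> ConfusionMatrix:
    """Count matrix ``counts[t][p]`` plus its row-normalized view."""
    y_true = np.asarray(true_labels, dtype=int)
    y_pred = np.asarray(predicted_labels, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors must have equal length")
    for arr in (y_true, y_pred):
        if len(arr) and (arr.min() < 0 or arr.max() >= n_classes):
            raise ValueError("label outside [0, n_classes)")
    counts = np.zeros((n_classes, n_classes))
    np.add.at(counts, (y_true, y_pred), 1.0)
    row_sums = counts.sum(axis=1, keepdims=True)
    normalized = np.divide(
        counts, row_sums, out=np.zeros_like(counts), where=row_sums > 0
    )
    return ConfusionMatrix(counts=counts, normalized=normalized)
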