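"""Per-residue ROC analysis for MoRF prediction.

Positives are MoRF residues and negatives all unmasked non-MoRF residues,
pooled across the dataset (micro-averaging): TPR = TP / N_MoRF and
FPR = FP / N_non-MoRF, with a positive call at threshold t defined as
score >= t.  Sensitivity is TPR; specificity is 1 - FPR.

Short/long evaluation masks MoRF intervals by length: in ``short_only``
mode intervals longer than 30 residues are masked out (removed from both
classes), in ``long_only`` mode intervals of up to 30 residues are.  The
AUC equals the trapezoidal area under the tie-grouped ROC curve, which is
identical to the Mann-Whitney concordance probability with half credit for
ties.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .tracks_io import MoRFAnnotation, ResidueTrack

#: MoRF intervals strictly longer than this count as "long".
LONG_MORF_CUTOFF = 30

MASK_MODES = ("all", "short_only", "long_only")


@dataclass
class LabeledScores:
    """Pooled (score, is_morf) residue pairs with masked residues removed."""

    scores: np.ndarray
    labels: np.ndarray  # boolean, True = MoRF

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float).ravel()
        self.labels = np.asarray(self.labels, dtype=bool).ravel()
        if self.scores.shape != self.labels.shape:
            raise ValueError("scores and labels have different lengths")
        if self.scores.size == 0:
            raise ValueError("no residues to evaluate")

    @property
    def n_morf(self) -> int:
        return int(self.labels.sum())

    @property
    def n_non_morf(self) -> int:
        return int((~self.labels).sum())

    def require_both_classes(self) -> None:
        if self.n_morf == 0 or self.n_non_morf == 0:
            raise ValueError(
                f"need residues of both classes, got {self.n_morf} MoRF and "
                f"{self.n_non_morf} non-MoRF"
            )


def pool_scores(results, annotations, mask_mode: str = "all") -> LabeledScores:
    """Pool per-residue scores and labels across a dataset.

    ``results`` is a mapping sequence id -> ResidueTrack, an iterable of
    such tracks, or an iterable of objects with ``sequence_id`` and a
    ``final`` ResidueTrack attribute (pipeline PredictionResult).
    ``annotations`` is a mapping or iterable of MoRFAnnotation.  Every
    scored sequence must be annotated.
    """
    if mask_mode not in MASK_MODES:
        raise ValueError(f"mask_mode must be one of {MASK_MODES}, got {mask_mode!r}")
    tracks = _as_track_mapping(results)
    ann_map = _as_annotation_mapping(annotations)

    scores_parts: list[np.ndarray] = []
    labels_parts: list[np.ndarray] = []
    for sid, track in tracks.items():
        if sid not in ann_map:
            raise ValueError(f"sequence {sid!r} is scored but has no annotation")
        labels = _masked_label_vector(ann_map[sid], len(track), mask_mode)
        keep = labels >= 0
        scores_parts.append(track.values[keep])
        labels_parts.append(labels[keep] == 1)
    return LabeledScores(np.concatenate(scores_parts), np.concatenate(labels_parts))


def _masked_label_vector(ann: MoRFAnnotation, length: int, mask_mode: str) -> np.ndarray:
    labels = ann.label_vector(length)
    if mask_mode == "all":
        return labels
    for start, end, lab in ann.intervals:
        if lab != "morf":
            continue
        interval_len = end - start + 1
        long = interval_len > LONG_MORF_CUTOFF
        if (mask_mode == "short_only" and long) or (
            mask_mode == "long_only" and not long
        ):
            labels[start - 1 : end] = -1
    return labels


# ---------------------------------------------------------------------------
# ROC machinery

def _roc_points(ls: LabeledScores) -> tuple[np.ndarray, np.ndarray]:
    """(FPR, TPR) at every distinct threshold, tie-grouped, from (0,0) to (1,1)."""
    ls.require_both_classes()
    order = np.argsort(-ls.scores, kind="stable")
    s = ls.scores[order]
    y = ls.labels[order]
    # last index of each tie group of equal scores
    boundaries = np.nonzero(np.diff(s))[0]
    last = np.concatenate([boundaries, [s.size - 1]])
    tp = np.cumsum(y)[last]
    fp = np.cumsum(~y)[last]
    tpr = np.concatenate([[0.0], tp / ls.n_morf])
    fpr = np.concatenate([[0.0], fp / ls.n_non_morf])
    return fpr, tpr


def roc_curve(ls: LabeledScores) -> list[tuple[float, float]]:
    """ROC_MoRF points as (FPR, TPR) pairs, monotone in both coordinates."""
    fpr, tpr = _roc_points(ls)
    return list(zip(fpr.tolist(), tpr.tolist()))


def auc_morf(ls: LabeledScores) -> float:
    """Area under the ROC_MoRF curve (trapezoidal)."""
    fpr, tpr = _roc_points(ls)
    return float(np.trapezoid(tpr, fpr))


def fpr_at_tpr(ls: LabeledScores, tpr_targets: Iterable[float]) -> list[float]:
    """Smallest achievable FPR among thresholds whose TPR >= each target."""
    targets = [float(t) for t in tpr_targets]
    for t in targets:
        if not 0.0 < t <= 1.0:
            raise ValueError(f"TPR target {t} outside (0, 1]")
    fpr, tpr = _roc_points(ls)
    out = []
    for t in targets:
        idx = int(np.searchsorted(tpr, t, side="left"))
        if idx >= tpr.size:
            raise ValueError(f"TPR target {t} unreachable")
        out.append(float(fpr[idx]))
    return out


def sens_spec_at_cutoff(ls: LabeledScores, cutoff: float) -> tuple[float, float]:
    """(sensitivity, specificity) with a positive call at score >= cutoff."""
    ls.require_both_classes()
    called = ls.scores >= cutoff
    tp = int(np.sum(called & ls.labels))
    fp = int(np.sum(called & ~ls.labels))
    sensitivity = tp / ls.n_morf
    specificity = 1.0 - fp / ls.n_non_morf
    return sensitivity, specificity


# ---------------------------------------------------------------------------

def _as_track_mapping(results) -> dict[str, ResidueTrack]:
    if isinstance(results, dict):
        items = results.items()
        return {sid: _final_track(obj) for sid, obj in items}
    out: dict[str, ResidueTrack] = {}
    for obj in results:
        track = _final_track(obj)
        out[track.sequence_id] = track
    return out


def _final_track(obj) -> ResidueTrack:
    if isinstance(obj, ResidueTrack):
        return obj
    final = getattr(obj, "final", None)
    if isinstance(final, ResidueTrack):
        return final
    raise TypeError(f"cannot extract a ResidueTrack from {type(obj).__name__}")


def _as_annotation_mapping(annotations) -> dict[str, MoRFAnnotation]:
    if isinstance(annotations, dict):
        return annotations
    return {ann.sequence_id: ann for ann in annotations}
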