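"""Evaluation of a rarity ranking against ground-truth event labels.

Ground truth is a set of labeled events (centroid plus phenotype category);
a tile is a positive iff at least one event centroid falls in its half-open
footprint, and the negative set is the complement over all tiles of the
slide. TPR/FPR at a cohort size, the full ROC obtained by sweeping the
cohort size from 0 to N, the trapezoidal AUROC, and pointwise quartile
summaries across slides follow from those definitions.

Tied rarity values are swept as one group (a single diagonal ROC segment),
which makes the trapezoidal AUROC exactly the Mann-Whitney probability that
a random positive outranks a random negative with ties counted 1/2.

The seven phenotype categories label positive signal per channel
(D-|CK denotes DAPI-negative, CK-positive — the oncosome-like class).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .rarity import RarityRanking
from .slide_io import SlideTiling

EVENT_CATEGORIES = (
    "D-|CK", "D|CK", "D|CK|V", "D|CK|V|CD", "D|V", "D|V|CD", "D|CK|CD",
)


@dataclass(frozen=True)
class EventLabel:
    event_id: int
    x: float
    y: float
    category: str

    def __post_init__(self) -> None:
        if self.category not in EVENT_CATEGORIES:
            raise ValueError(
                f"unknown category {self.category!r}; expected one of "
                f"{EVENT_CATEGORIES}")


class LabeledTiling:
    """Positive/negative flag per tile plus contributing categories."""

    def __init__(self, n_tiles: int, positive: np.ndarray,
                 categories: dict[int, set[str]]) -> None:
        self.n_tiles = n_tiles
        self.positive = np.asarray(positive, dtype=bool)
        self.categories = categories

    @property
    def positives(self) -> np.ndarray:
        return np.flatnonzero(self.positive)

    @property
    def n_positive(self) -> int:
        return int(self.positive.sum())

    def restricted_to(self, category: str) -> "LabeledTiling":
        """Labels for one phenotype category only."""
        pos = np.zeros(self.n_tiles, dtype=bool)
        cats = {}
        for tid, cs in self.categories.items():
            if category in cs:
                pos[tid] = True
                cats[tid] = {category}
        return LabeledTiling(self.n_tiles, pos, cats)


@dataclass(frozen=True)
class ROCCurve:
    """Ordered (FPR, TPR) points from (0,0) to (1,1), both non-decreasing."""

    fpr: np.ndarray
    tpr: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.fpr) < 0) or np.any(np.diff(self.tpr) < 0):
            raise ValueError("ROC coordinates must be non-decreasing")


def label_tiles(events: list[EventLabel], tiling: SlideTiling) -> LabeledTiling:
    """Attach ground truth to tiles by centroid containment.

    An event whose centroid lies in a discarded frame margin (or outside the
    slide) cannot be assigned to a tile and is dropped with a warning.
    """
    positive = np.zeros(len(tiling), dtype=bool)
    categories: dict[int, set[str]] = {}
    for ev in events:
        tid = tiling.tile_of_point(ev.x, ev.y)
        if tid is None:
            warnings.warn(
                f"event {ev.event_id} at ({ev.x}, {ev.y}) lies outside the "
                f"tiled region; dropped", stacklevel=2)
            continue
        positive[tid] = True
        categories.setdefault(tid, set()).add(ev.category)
    return LabeledTiling(len(tiling), positive, categories)


def tpr_fpr_at(cohort: np.ndarray, labels: LabeledTiling) -> tuple[float, float]:
    """True/false positive rates of a cohort of tile ids.

    TPR = |cohort intersect positives| / |positives|;
    FPR = |cohort intersect negatives| / |negatives| where the negatives are
    all non-positive tiles of the slide.
    """
    n_pos = labels.n_positive
    n_neg = labels.n_tiles - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError(
            f"evaluation needs at least one positive and one negative tile "
            f"(got {n_pos} positives, {n_neg} negatives)")
    cohort = np.asarray(cohort, dtype=np.int64)
    in_pos = labels.positive[cohort]
    tp = int(in_pos.sum())
    fp = len(cohort) - tp
    return tp / n_pos, fp / n_neg


def roc_curve(ranking: RarityRanking, labels: LabeledTiling) -> ROCCurve:
    """ROC obtained by sweeping the cohort size over the full ranking.

    Groups of tiles with identical rarity enter as one step, so the curve
    (and its trapezoidal area) is invariant to the arbitrary id-order within
    a tie group.
    """
    n_pos = labels.n_positive
    n_neg = labels.n_tiles - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("evaluation needs >= 1 positive and >= 1 negative tile")
    is_pos = labels.positive[ranking.tile_ids]
    # boundaries of tied-rarity groups along the descending order
    r = ranking.rarity
    boundary = np.flatnonzero(np.diff(r) != 0) + 1
    edges = np.concatenate(([0], boundary, [len(r)]))
    cum_tp = np.concatenate(([0], np.cumsum(is_pos)))
    counts = np.arange(len(r) + 1)
    tp_at = cum_tp[edges]
    fp_at = counts[edges] - tp_at
    return ROCCurve(fp_at / n_neg, tp_at / n_pos)


def auroc(curve: ROCCurve) -> float:
    """Trapezoidal area under the ROC curve."""
    return float(np.trapezoid(curve.tpr, curve.fpr))


def quartile_curves(curves: list[ROCCurve],
                    fpr_grid: np.ndarray) -> tuple[ROCCurve, ROCCurve, ROCCurve]:
    """Pointwise lower-quartile / median / upper-quartile ROC across slides.

    Each curve is linearly interpolated onto the common FPR grid (taking the
    maximal TPR where a curve has a vertical segment); percentiles use
    linear interpolation between order statistics.
    """
    if not curves:
        raise ValueError("need at least one ROC curve")
    fpr_grid = np.asarray(fpr_grid, dtype=float)
    interped = []
    for c in curves:
        # collapse vertical segments: keep the max TPR at each distinct FPR
        fpr, idx = np.unique(c.fpr[::-1], return_index=True)
        tpr = c.tpr[::-1][idx]
        interped.append(np.interp(fpr_grid, fpr, tpr))
    stack = np.vstack(interped)
    q25, q50, q75 = np.percentile(stack, [25, 50, 75], axis=0)
    return (ROCCurve(fpr_grid, q25), ROCCurve(fpr_grid, q50),
            ROCCurve(fpr_grid, q75))


def evaluate_ranking(ranking: RarityRanking, labels: LabeledTiling,
                     cohort: np.ndarray) -> dict[str, float]:
    """Summary metrics: overall and per-category TPR at the cohort plus AUROC."""
    out: dict[str, float] = {}
    tpr, fpr = tpr_fpr_at(cohort, labels)
    out["tpr"] = tpr
    out["fpr"] = fpr
    out["auroc"] = auroc(roc_curve(ranking, labels))
    for cat in EVENT_CATEGORIES:
        sub = labels.restricted_to(cat)
        if sub.n_positive == 0:
            continue
        t, _ = tpr_fpr_at(cohort, sub)
        out[f"tpr[{cat}]"] = t
        out[f"auroc[{cat}]"] = auroc(roc_curve(ranking, sub))
    return out
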