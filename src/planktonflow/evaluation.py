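"""Scoring detections against ground truth, count statistics, threshold sweeps.

Object-level scoring uses greedy one-to-one centroid matching (the reference
ground truth for this kind of footage is a manual count, not pixel masks):
detection/truth pairs are accepted in order of ascending centroid distance,
up to a match radius.  Matched pairs are true positives; leftover detections
are false positives, leftover truths false negatives.

Count summaries use the *population* standard deviation (÷n).

The threshold sweep reproduces the dual-threshold grid search: for every
(β1, β2) cell the detector is re-thresholded (flow fields are solved once)
and scored by the cosine similarity between the original frame and the
masked frame, averaged over evaluated frames; larger scores mean the mask
retains an image more similar to the original.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .detect import DetectionResult, DetectorConfig, label_components, opposition_mask
from .detect import _pair_flow, _subsample, _upsample_mask  # shared pipeline internals
from .flow import FlowPair
from .frames import GrayFrame
from .synthetic import BlobTruth

__all__ = [
    "ConfusionCounts",
    "PRF1",
    "SweepTable",
    "match_detections",
    "precision_recall_f1",
    "f1_score",
    "summarize_counts",
    "cosine_score",
    "threshold_sweep",
    "DEFAULT_BETA1_GRID",
    "DEFAULT_BETA2_GRID",
]

#: Default sweep grids: β1 from 0.05 to 0.35 in steps of 0.05, β2 from 3 to 9
#: in steps of 1.
DEFAULT_BETA1_GRID = tuple(round(0.05 * k, 2) for k in range(1, 8))
DEFAULT_BETA2_GRID = tuple(float(b) for b in range(3, 10))


@dataclass(frozen=True)
class ConfusionCounts:
    """Object-detection confusion counts (tn kept for completeness; it is
    undefined for object detection and stays 0)."""

    tp: int
    fp: int
    fn: int
    tn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp, self.fn + other.fn, self.tn + other.tn
        )


class PRF1(NamedTuple):
    precision: float
    recall: float
    f1: float


def match_detections(
    pred: DetectionResult,
    truth_blobs: Sequence[BlobTruth],
    match_radius: float | None = None,
) -> ConfusionCounts:
    """Greedy one-to-one centroid matching of detections against truth.

    ``match_radius`` defaults to each truth blob's radius + 2 px.  Ties in
    distance are broken by the lower detection label, then the lower truth
    index, making the outcome deterministic.  Conservation laws:
    tp + fp = number of detections, tp + fn = number of truth objects.
    """
    det = [(c.label, c.centroid_x, c.centroid_y) for c in pred.components]
    candidates = []
    for ti, tb in enumerate(truth_blobs):
        radius = (tb.radius + 2.0) if match_radius is None else float(match_radius)
        for label, cx, cy in det:
            dist = math.hypot(cx - tb.centroid_x, cy - tb.centroid_y)
            if dist <= radius:
                candidates.append((dist, label, ti))
    candidates.sort()
    used_det: set[int] = set()
    used_truth: set[int] = set()
    tp = 0
    for _, label, ti in candidates:
        if label in used_det or ti in used_truth:
            continue
        used_det.add(label)
        used_truth.add(ti)
        tp += 1
    return ConfusionCounts(tp=tp, fp=len(det) - tp, fn=len(truth_blobs) - tp)


def precision_recall_f1(c: ConfusionCounts) -> PRF1:
    """Precision = TP/(TP+FP), Recall = TP/(TP+FN), F1 = 2PR/(P+R).

    An undefined metric (empty denominator) is returned as NaN, never as a
    silent 0; the single stated convention is F1 = 0 when P + R = 0.
    """
    precision = c.tp / (c.tp + c.fp) if (c.tp + c.fp) > 0 else math.nan
    recall = c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else math.nan
    return PRF1(precision, recall, f1_score(precision, recall))


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    if math.isnan(precision) or math.isnan(recall):
        return math.nan
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def summarize_counts(counts: Sequence[float]) -> tuple[float, float]:
    """Mean and population standard deviation (÷n) of a count series."""
    if len(counts) == 0:
        raise ValueError("summarize_counts needs a nonempty list")
    arr = np.asarray(counts, dtype=np.float64)
    return float(arr.mean()), float(arr.std(ddof=0))


def cosine_score(
    original: GrayFrame | np.ndarray,
    mask: DetectionResult | np.ndarray,
    binary: bool = False,
) -> float:
    """Cosine similarity between the original frame and its masked version.

    The masked vector keeps the original intensity where the mask is true
    and 0 elsewhere (``binary=True`` compares against the 0/1 mask instead).
    Returns 0 if either vector has zero norm.
    """
    img = original.pixels if isinstance(original, GrayFrame) else np.asarray(original, float)
    m = mask.mask if isinstance(mask, DetectionResult) else np.asarray(mask, bool)
    if img.shape != m.shape:
        raise ValueError(f"shape mismatch: frame {img.shape} vs mask {m.shape}")
    a = img.ravel()
    b = (m.astype(np.float64) if binary else img * m).ravel()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        return 0.0
    return float(a @ b / (na * nb))


@dataclass(frozen=True)
class SweepTable:
    """Grid-search result: scores[i, j] is the cell (β2=beta2_grid[i],
    β1=beta1_grid[j])."""

    beta1_grid: tuple[float, ...]
    beta2_grid: tuple[float, ...]
    scores: np.ndarray

    def __post_init__(self) -> None:
        expect = (len(self.beta2_grid), len(self.beta1_grid))
        if self.scores.shape != expect:
            raise ValueError(f"score matrix must be {expect}, got {self.scores.shape}")
        if np.any(self.scores < -1 - 1e-12) or np.any(self.scores > 1 + 1e-12):
            raise ValueError("cosine scores must lie in [-1, 1]")

    @property
    def argmax(self) -> tuple[float, float]:
        """(β1, β2) of the best-scoring cell (first in scan order on ties)."""
        i, j = np.unravel_index(int(np.argmax(self.scores)), self.scores.shape)
        return self.beta1_grid[j], self.beta2_grid[i]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.scores, index=list(self.beta2_grid), columns=list(self.beta1_grid)
        )


def threshold_sweep(
    frames: Sequence[GrayFrame],
    cfg_base: DetectorConfig = DetectorConfig(),
    beta1_grid: Sequence[float] = DEFAULT_BETA1_GRID,
    beta2_grid: Sequence[float] = DEFAULT_BETA2_GRID,
    binary: bool = False,
) -> SweepTable:
    """Average cosine score of the detector over a (β1, β2) grid.

    Flow fields are solved once for the sequence and re-thresholded per
    cell, so the sweep costs one flow pass plus |grid| maskings.
    """
    kept = list(frames)[:: cfg_base.frame_stride]
    if len(kept) < 3:
        raise ValueError("threshold_sweep needs at least 3 frames")
    p = cfg_base.pixel_stride
    coarse = [_subsample(f, p) for f in kept]
    flows = [_pair_flow(coarse[i], coarse[i + 1], cfg_base) for i in range(len(coarse) - 1)]
    pairs = [FlowPair(first=flows[t - 1], second=flows[t]) for t in range(1, len(kept) - 1)]

    scores = np.zeros((len(beta2_grid), len(beta1_grid)))
    for i, b2 in enumerate(beta2_grid):
        for j, b1 in enumerate(beta1_grid):
            cell = []
            for t, pair in enumerate(pairs, start=1):
                mask = opposition_mask(
                    pair, beta1=b1, beta2=b2,
                    flow_scale=cfg_base.flow_scale, combine=cfg_base.combine,
                )
                mask = _upsample_mask(mask, p, kept[t].shape)
                res = label_components(
                    mask, connectivity=cfg_base.connectivity,
                    min_area=cfg_base.min_area, frame_index=kept[t].index,
                )
                cell.append(cosine_score(kept[t], res, binary=binary))
            scores[i, j] = float(np.mean(cell))
    return SweepTable(
        beta1_grid=tuple(float(b) for b in beta1_grid),
        beta2_grid=tuple(float(b) for b in beta2_grid),
        scores=scores,
    )
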