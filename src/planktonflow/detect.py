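"""Opposite-flow plankton detection: dual thresholding, labeling, sequencing.

A pixel belongs to a fast-moving plankton when its two consecutive flow
values are (nearly) opposite *and* genuinely nonzero.  Two thresholds encode
this: β1 tolerates the near-but-not-exact cancellation of real footage
(|u + u′| < β1), and β2 rejects the pixels where both flows merely happen to
be small (−u·u′ > β2) — without β2 the whole static background would satisfy
the β1 inequality.  Connected components of the marked pixels are the
detected plankton; the component count is the plankton count.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage

from .flow import FlowPair, compute_gradients, hs_solve
from .frames import GrayFrame

__all__ = [
    "DetectorConfig",
    "Component",
    "DetectionResult",
    "opposition_mask",
    "label_components",
    "detect_sequence",
    "with_thresholds",
]

_STRUCT4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
_STRUCT8 = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class DetectorConfig:
    """All knobs of the detection pipeline.

    beta1 : opposition-sum tolerance (flow units); must lie in (0, 10).
    beta2 : anti-null product floor (squared flow units), > 0.
    flow_scale : normalizer s applied to the β2 inequality as −u·u′ > β2·s²;
        the default 1 gives the raw inequality.
    combine : how the per-axis inequalities join. ``axis_and_then_or``
        (default) requires the sum and product tests to hold on the *same*
        axis, then ORs across axes — the only combination in which β2
        actually suppresses the small-flow false positives axis by axis.
        ``joint_or`` is the literal reading (OR over axes within each
        inequality, AND between the two).
    alpha2, n_iters, cube_mean, neighborhood_average, include_center are
    forwarded to the flow solver.  pixel_stride p computes flow on every
    p-th row/column; frame_stride s keeps every s-th frame.
    """

    beta1: float = 0.35
    beta2: float = 3.0
    alpha2: float = 100.0
    n_iters: int = 100
    connectivity: Literal[4, 8] = 8
    min_area: int = 2
    pixel_stride: int = 1
    frame_stride: int = 1
    flow_scale: float = 1.0
    combine: Literal["axis_and_then_or", "joint_or"] = "axis_and_then_or"
    cube_mean: bool = False
    neighborhood_average: bool = False
    include_center: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.beta1 < 10:
            raise ValueError(f"beta1 must lie in (0, 10), got {self.beta1}")
        if self.beta2 <= 0:
            raise ValueError(f"beta2 must be > 0, got {self.beta2}")
        if self.connectivity not in (4, 8):
            raise ValueError(f"connectivity must be 4 or 8, got {self.connectivity}")
        if self.min_area < 1:
            raise ValueError(f"min_area must be >= 1, got {self.min_area}")
        if self.pixel_stride < 1 or self.frame_stride < 1:
            raise ValueError("strides must be positive integers")
        if self.flow_scale <= 0:
            raise ValueError(f"flow_scale must be > 0, got {self.flow_scale}")
        if self.combine not in ("axis_and_then_or", "joint_or"):
            raise ValueError(f"unknown combine mode {self.combine!r}")


@dataclass(frozen=True)
class Component:
    """One detected plankton: label, centroid (x=col, y=row) and pixel count."""

    label: int
    centroid_x: float
    centroid_y: float
    n_pixels: int


@dataclass(frozen=True)
class DetectionResult:
    """Per-frame detection output."""

    frame_index: int
    mask: np.ndarray
    labels: np.ndarray
    components: tuple[Component, ...] = field(default_factory=tuple)

    @property
    def n_components(self) -> int:
        return len(self.components)

    @property
    def centroids(self) -> np.ndarray:
        """(n, 2) array of (x, y) centroids."""
        return np.array([(c.centroid_x, c.centroid_y) for c in self.components]).reshape(-1, 2)


def opposition_mask(
    pair: FlowPair,
    beta1: float = 0.35,
    beta2: float = 3.0,
    flow_scale: float = 1.0,
    combine: str = "axis_and_then_or",
) -> np.ndarray:
    """Boolean grid of pixels whose consecutive flows are genuinely opposite.

    Per axis the test is |u + u′| < β1 (near-cancellation) together with
    −u·u′ > β2·s² (both flows nonzero and of opposite sign).  The absolute
    value on the sum is deliberate: the bare inequality u + u′ < β1 would
    mark any strongly negative sum, defeating its purpose as a tolerance
    around zero.
    """
    if beta1 <= 0 or beta2 <= 0:
        raise ValueError(f"thresholds must be positive, got beta1={beta1}, beta2={beta2}")
    u, v = pair.first.u, pair.first.v
    up, vp = pair.second.u, pair.second.v
    s2 = flow_scale * flow_scale
    sum_u = np.abs(u + up) < beta1
    sum_v = np.abs(v + vp) < beta1
    prod_u = -(u * up) > beta2 * s2
    prod_v = -(v * vp) > beta2 * s2
    if combine == "axis_and_then_or":
        return (sum_u & prod_u) | (sum_v & prod_v)
    if combine == "joint_or":
        return (sum_u | sum_v) & (prod_u | prod_v)
    raise ValueError(f"unknown combine mode {combine!r}")


def label_components(
    mask: np.ndarray,
    connectivity: int = 8,
    min_area: int = 2,
    frame_index: int = 0,
) -> DetectionResult:
    """Connected-component labeling with a minimum-size filter.

    Components smaller than ``min_area`` pixels are discarded (single-pixel
    flicker suppression; pass 1 to disable).  Surviving components are
    relabeled 1..n in scan order; centroids are arithmetic means of member
    pixel coordinates.
    """
    mask = np.asarray(mask, dtype=bool)
    struct = _STRUCT8 if connectivity == 8 else _STRUCT4
    lab, n = ndimage.label(mask, structure=struct)
    comps: list[Component] = []
    if n:
        idx = np.arange(1, n + 1)
        sizes = ndimage.sum_labels(mask, lab, index=idx).astype(int)
        keep = idx[sizes >= min_area]
        relab = np.zeros(n + 1, dtype=np.int32)
        relab[keep] = np.arange(1, len(keep) + 1)
        lab = relab[lab]
        if len(keep):
            centers = ndimage.center_of_mass(mask, lab, index=np.arange(1, len(keep) + 1))
            for new_label, (cy, cx) in enumerate(centers, start=1):
                comps.append(
                    Component(
                        label=new_label,
                        centroid_x=float(cx),
                        centroid_y=float(cy),
                        n_pixels=int(sizes[keep[new_label - 1] - 1]),
                    )
                )
    final_mask = lab > 0
    return DetectionResult(
        frame_index=frame_index, mask=final_mask, labels=lab, components=tuple(comps)
    )


def _pair_flow(a: GrayFrame, b: GrayFrame, cfg: DetectorConfig):
    grad = compute_gradients(a, b, cube_mean=cfg.cube_mean)
    return hs_solve(
        grad,
        alpha2=cfg.alpha2,
        n_iters=cfg.n_iters,
        neighborhood_average=cfg.neighborhood_average,
        include_center=cfg.include_center,
    )


def _subsample(frame: GrayFrame, p: int) -> GrayFrame:
    if p == 1:
        return frame
    return GrayFrame(frame.pixels[::p, ::p], index=frame.index)


def _upsample_mask(mask: np.ndarray, p: int, shape: tuple[int, int]) -> np.ndarray:
    if p == 1:
        return mask
    up = np.repeat(np.repeat(mask, p, axis=0), p, axis=1)
    return up[: shape[0], : shape[1]]


def detect_sequence(
    frames: Sequence[GrayFrame], cfg: DetectorConfig = DetectorConfig()
) -> list[DetectionResult]:
    """Run the full detector over a frame sequence.

    Applies ``cfg.frame_stride`` subsampling, then emits one
    :class:`DetectionResult` per interior frame t of the kept sequence,
    built from the triple (t−1, t, t+1).  Each consecutive-pair flow field
    is computed once and shared between the two triples that use it.  With
    ``pixel_stride`` p > 1 the flow is solved on the p-subsampled grid and
    the resulting mask is upsampled by nearest neighbor to full resolution
    before labeling.  Result ``frame_index`` values are the original frame
    indices of the mid frames.
    """
    kept = list(frames)[:: cfg.frame_stride]
    if len(kept) < 3:
        raise ValueError(
            f"need >= 3 frames after frame_stride={cfg.frame_stride}, got {len(kept)}"
        )
    p = cfg.pixel_stride
    coarse = [_subsample(f, p) for f in kept]
    results: list[DetectionResult] = []
    try:
        flows = [_pair_flow(coarse[i], coarse[i + 1], cfg) for i in range(len(coarse) - 1)]
        for t in range(1, len(kept) - 1):
            pair = FlowPair(first=flows[t - 1], second=flows[t])
            mask = opposition_mask(
                pair,
                beta1=cfg.beta1,
                beta2=cfg.beta2,
                flow_scale=cfg.flow_scale,
                combine=cfg.combine,
            )
            mask = _upsample_mask(mask, p, kept[t].shape)
            results.append(
                label_components(
                    mask,
                    connectivity=cfg.connectivity,
                    min_area=cfg.min_area,
                    frame_index=kept[t].index,
                )
            )
    except Exception as exc:
        frame_at = kept[len(results) + 1].index if len(results) + 1 < len(kept) else -1
        raise RuntimeError(f"detection failed at frame {frame_at}: {exc}") from exc
    return results


def with_thresholds(cfg: DetectorConfig, beta1: float, beta2: float) -> DetectorConfig:
    """A copy of ``cfg`` with the dual thresholds replaced."""
    return replace(cfg, beta1=beta1, beta2=beta2)
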