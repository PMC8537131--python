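"""Physical quantification: pixel counts → areas (m²) → equivalent-sphere volumes (m³).

A detected component of N pixels covers the physical area

    S = N · (W / width) · (H / height)

where W × H meters is the camera field of view imaged at width × height
pixels.  The 3D size of an irregular organism is approximated by the sphere
whose great-circle area equals S, i.e. radius r = √(S/π) and

    V = (4/3) · π^(−1/2) · S^(3/2)

which lets a projected area stand in for a volume without any shape model.
Volumes are computed per component and then summed — V is nonlinear in S, so
converting a summed area would understate multi-organism totals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .detect import DetectionResult

__all__ = [
    "CameraGeometry",
    "QuantSeries",
    "component_area",
    "equivalent_volume",
    "aggregate_series",
]


@dataclass(frozen=True)
class CameraGeometry:
    """Field-of-view calibration: physical extent (m) and frame size (px)."""

    fov_w: float
    fov_h: float
    width: int
    height: int

    def __post_init__(self) -> None:
        if min(self.fov_w, self.fov_h, self.width, self.height) <= 0:
            raise ValueError(
                f"all geometry values must be strictly positive, got {self}"
            )

    @property
    def pixel_area(self) -> float:
        """Physical area of one pixel, m²."""
        return (self.fov_w / self.width) * (self.fov_h / self.height)


def component_area(n_pixels: int, geom: CameraGeometry) -> float:
    """Physical area S (m²) of a component of ``n_pixels`` pixels."""
    if n_pixels < 0:
        raise ValueError(f"pixel count must be >= 0, got {n_pixels}")
    return n_pixels * geom.pixel_area


def equivalent_volume(area: float) -> float:
    """Equivalent-sphere volume V (m³) of projected area ``area`` (m²).

    V = (4/3)·π^(−1/2)·S^(3/2), identically the volume of the sphere of
    radius √(S/π).  Strictly increasing, with V(kS) = k^(3/2) V(S).
    """
    if area < 0:
        raise ValueError(f"area must be >= 0, got {area}")
    return (4.0 / 3.0) * math.pi ** (-0.5) * area**1.5


@dataclass(frozen=True)
class QuantSeries:
    """Per-frame count / total-area / total-volume time series."""

    frame_index: tuple[int, ...]
    counts: tuple[int, ...]
    total_area: tuple[float, ...]
    total_volume: tuple[float, ...]

    def __post_init__(self) -> None:
        n = len(self.frame_index)
        if not (len(self.counts) == len(self.total_area) == len(self.total_volume) == n):
            raise ValueError("series columns must have equal lengths")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame_index": self.frame_index,
                "n_plankton": self.counts,
                "total_area_m2": self.total_area,
                "total_volume_m3": self.total_volume,
            }
        )


def aggregate_series(
    results: Sequence[DetectionResult], geom: CameraGeometry
) -> QuantSeries:
    """Count, total area and total equivalent volume per frame.

    Volume is the sum of per-component equivalent-sphere volumes (see module
    docstring for why the order of summing matters).
    """
    idx, counts, areas, vols = [], [], [], []
    for res in results:
        comp_areas = [component_area(c.n_pixels, geom) for c in res.components]
        idx.append(res.frame_index)
        counts.append(res.n_components)
        areas.append(float(sum(comp_areas)))
        vols.append(float(sum(equivalent_volume(s) for s in comp_areas)))
    return QuantSeries(
        frame_index=tuple(idx),
        counts=tuple(counts),
        total_area=tuple(areas),
        total_volume=tuple(vols),
    )
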