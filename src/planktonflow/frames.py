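"""Frame ingestion: reading video/image sequences, grayscale conversion, padding.

All downstream computation works on :class:`GrayFrame` objects — 2D real-valued
intensity grids.  The coordinate convention throughout the package is
``x`` = column index (increasing rightward), ``y`` = row index (increasing
downward), both 0-based; arrays are indexed ``pixels[y, x]``.
"""

from __future__ import annotations

import glob as _glob
import os
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "GrayFrame",
    "FrameTriple",
    "BT601_WEIGHTS",
    "to_grayscale",
    "pad_pair",
    "read_frames",
    "frames_from_arrays",
]

#: ITU-R BT.601 luma weights (R, G, B) — the default channel weighting.
BT601_WEIGHTS = (0.299, 0.587, 0.114)


@dataclass(frozen=True)
class GrayFrame:
    """A single grayscale video frame.

    Parameters
    ----------
    pixels
        2D float array of intensities (nominally 0–255, held as reals —
        the flow relaxation is real-valued, so intensities are never
        re-quantized after conversion).
    index
        Temporal index ``t`` of the frame (integer ≥ 0).
    """

    pixels: np.ndarray
    index: int = 0

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2:
            raise ValueError(f"GrayFrame needs a 2D grid, got ndim={px.ndim}")
        if px.shape[0] < 2 or px.shape[1] < 2:
            raise ValueError(
                f"frame must be at least 2x2 (gradients need an x+1/y+1 "
                f"neighbor), got {px.shape}"
            )
        if not np.all(np.isfinite(px)):
            raise ValueError("frame intensities must be finite")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class FrameTriple:
    """Three consecutive frames (t−1, t, t+1): the detector's atomic input."""

    prev: GrayFrame
    mid: GrayFrame
    next: GrayFrame

    def __post_init__(self) -> None:
        if not (self.prev.shape == self.mid.shape == self.next.shape):
            raise ValueError(
                f"triple frames must share a shape, got "
                f"{self.prev.shape}/{self.mid.shape}/{self.next.shape}"
            )
        if not (self.prev.index < self.mid.index < self.next.index):
            raise ValueError("triple frame indices must be increasing")


def to_grayscale(
    frame: np.ndarray,
    weights: Sequence[float] = BT601_WEIGHTS,
    index: int = 0,
) -> GrayFrame:
    """Convert an RGB frame to grayscale by channel weighting.

    A frame that is already 2D passes through unchanged.  ``weights`` must be
    three nonnegative reals summing to 1 (default: BT.601 luma); the output
    pixel is the weighted sum of the channel values, so the conversion is
    linear and bounded by the min/max of the input channels.
    """
    arr = np.asarray(frame, dtype=np.float64)
    if arr.ndim == 2:
        return GrayFrame(arr, index=index)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"expected HxW or HxWx3 frame, got shape {arr.shape}")
    w = np.asarray(weights, dtype=np.float64)
    if w.shape != (3,):
        raise ValueError("weights must have length 3")
    if np.any(w < 0) or abs(float(w.sum()) - 1.0) > 1e-9:
        raise ValueError(
            f"grayscale weights must be nonnegative and sum to 1, got {tuple(w)}"
        )
    return GrayFrame(arr @ w, index=index)


def pad_pair(a: GrayFrame, b: GrayFrame) -> np.ndarray:
    """Stack two frames into the padded (height+1)×(width+1)×2 block.

    The last row and column of each frame are replicated, so the 2×2×2
    gradient kernels are defined at every original pixel with ``x+1``/``y+1``
    always in range, and border gradients depend only on real pixels (edge
    replication introduces zero artificial contrast).
    """
    if a.shape != b.shape:
        raise ValueError(f"pad_pair needs equal shapes, got {a.shape} vs {b.shape}")
    block = np.empty((a.height + 1, a.width + 1, 2), dtype=np.float64)
    for k, frame in enumerate((a, b)):
        block[:, :, k] = np.pad(frame.pixels, ((0, 1), (0, 1)), mode="edge")
    return block


def frames_from_arrays(arrays: Sequence[np.ndarray], start_index: int = 0) -> list[GrayFrame]:
    """Wrap a stack of 2D arrays as consecutively indexed GrayFrames."""
    return [GrayFrame(a, index=start_index + i) for i, a in enumerate(arrays)]


def _is_pattern(source: str) -> bool:
    return any(ch in source for ch in "*?[")


def read_frames(
    source: str | os.PathLike,
    frame_stride: int = 1,
    weights: Sequence[float] = BT601_WEIGHTS,
) -> list[GrayFrame]:
    """Read a video file, directory or glob of images as grayscale frames.

    ``frame_stride`` s keeps frames 0, s, 2s, … of the decoded sequence
    (⌈N/s⌉ frames for an N-frame source); the returned :class:`GrayFrame`
    indices are the *kept-sequence* positions 0, 1, 2, … so downstream
    triples see consecutive indices.  Image files matched by a directory or
    glob pattern are ordered lexicographically.

    Raises ``IOError`` naming the path for unreadable sources and
    ``ValueError`` if fewer than 3 frames remain after striding.
    """
    import imageio.v3 as iio

    if frame_stride < 1:
        raise ValueError(f"frame_stride must be a positive integer, got {frame_stride}")
    src = os.fspath(source)

    raw: list[np.ndarray] = []
    if os.path.isdir(src) or _is_pattern(src):
        pattern = os.path.join(src, "*") if os.path.isdir(src) else src
        paths = sorted(p for p in _glob.glob(pattern) if os.path.isfile(p))
        if not paths:
            raise IOError(f"no image files match {src!r}")
        for p in paths:
            try:
                raw.append(np.asarray(iio.imread(p)))
            except Exception as exc:  # noqa: BLE001 - re-raise with the path named
                raise IOError(f"could not read image {p!r}: {exc}") from exc
    else:
        if not os.path.exists(src):
            raise IOError(f"input source {src!r} does not exist")
        try:
            for frame in iio.imiter(src):
                raw.append(np.asarray(frame))
        except Exception as exc:  # noqa: BLE001
            raise IOError(f"could not decode video {src!r}: {exc}") from exc

    kept = raw[::frame_stride]
    if len(kept) < 3:
        raise ValueError(
            f"need at least 3 frames after frame_stride={frame_stride}, "
            f"got {len(kept)} (source {src!r} decoded {len(raw)})"
        )
    out = []
    for i, arr in enumerate(kept):
        if arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha
            arr = arr[:, :, :3]
        out.append(to_grayscale(arr, weights=weights, index=i))
    return out
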