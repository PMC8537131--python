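"""Synthetic underwater scenes with exact ground truth.

Real deep-sea dive footage of plankton is rarely shareable, so this module
generates seeded stand-in videos that satisfy — or deliberately violate —
the assumptions of the opposite-flow detector:

* a background that is locally time-invariant (``constant``/``texture``) or
  slowly drifting (``drift``, approximating camera motion);
* small bright hard-edged disks ("plankton") whose per-frame displacement
  exceeds their diameter in ``fast`` mode, the non-overlap premise of the
  detection theory;
* an optional diffuse, low-contrast, slowly moving "sediment cloud"
  distractor;
* additive Gaussian sensor noise, applied last.

All randomness flows from one integer seed through numpy ``SeedSequence``
spawning (PCG64), so a scene regenerates bit-identically on any platform;
each blob gets its own child stream.  Truth masks record exactly the pixels
whose intensity a blob modified.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .frames import FrameTriple, GrayFrame

__all__ = [
    "BackgroundConfig",
    "BlobConfig",
    "SedimentConfig",
    "SceneConfig",
    "BlobTruth",
    "SceneTruth",
    "generate_scene",
    "generate_triple",
]


@dataclass(frozen=True)
class BackgroundConfig:
    mode: Literal["constant", "texture", "drift"] = "constant"
    level: float = 30.0
    texture_contrast: float = 8.0
    texture_scale: float = 6.0
    drift_velocity: tuple[float, float] = (0.5, 0.2)  # (vx, vy) px/frame

    def __post_init__(self) -> None:
        if self.mode not in ("constant", "texture", "drift"):
            raise ValueError(f"background.mode: unknown mode {self.mode!r}")
        if not 0 <= self.level <= 255:
            raise ValueError(f"background.level: must be in [0, 255], got {self.level}")


@dataclass(frozen=True)
class BlobConfig:
    """Plankton stand-ins: hard disks of constant intensity offset.

    ``fast=True`` enforces the non-overlap premise: every per-frame
    displacement is at least 2·radius + 2 px (diameter plus a 1-px gradient
    stencil margin), so consecutive truth masks are disjoint.  When
    ``displacement_range`` is None it defaults per blob to
    (2r + 2, 2r + 6) in fast mode and (1, r) otherwise.
    """

    count: int = 8
    radius_range: tuple[int, int] = (2, 4)
    offset_range: tuple[float, float] = (60.0, 100.0)
    displacement_range: tuple[float, float] | None = None
    fast: bool = True
    soft_edge_sigma: float = 0.0  # >0 smooths the disk edge (robustness tests)

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError(f"blobs.count: must be >= 0, got {self.count}")
        if self.radius_range[0] < 1 or self.radius_range[0] > self.radius_range[1]:
            raise ValueError(f"blobs.radius_range: invalid {self.radius_range}")
        if self.offset_range[0] <= 0 or self.offset_range[0] > self.offset_range[1]:
            raise ValueError(f"blobs.offset_range: invalid {self.offset_range}")

    def displacement_bounds(self, radius: int) -> tuple[float, float]:
        if self.displacement_range is not None:
            lo, hi = self.displacement_range
        elif self.fast:
            lo, hi = 2 * radius + 2, 2 * radius + 6
        else:
            lo, hi = 1.0, float(max(radius, 1))
        if self.fast and lo < 2 * radius + 1:
            raise ValueError(
                f"blobs.displacement_range: fast mode requires a minimum "
                f"displacement >= 2*radius+1 = {2 * radius + 1}, got {lo}"
            )
        return float(lo), float(hi)


@dataclass(frozen=True)
class SedimentConfig:
    """Diffuse low-contrast moving distractor (a smoothed bright patch)."""

    enabled: bool = False
    extent: float = 18.0  # Gaussian envelope sigma, px
    contrast: float = 20.0  # peak intensity offset
    velocity: tuple[float, float] = (1.5, 0.5)  # px/frame

    def __post_init__(self) -> None:
        if self.enabled and (self.extent <= 0 or self.contrast <= 0):
            raise ValueError("sediment_cloud: extent and contrast must be > 0 when enabled")


@dataclass(frozen=True)
class SceneConfig:
    """Full description of a synthetic scene; the default is the package's
    reference study condition (20 frames of 128×128, 8 fast blobs, σ=1 noise,
    seed 7)."""

    n_frames: int = 20
    height: int = 128
    width: int = 128
    background: BackgroundConfig = field(default_factory=BackgroundConfig)
    blobs: BlobConfig = field(default_factory=BlobConfig)
    sediment: SedimentConfig = field(default_factory=SedimentConfig)
    noise_sigma: float = 1.0
    seed: int = 7

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError(f"n_frames: must be >= 1, got {self.n_frames}")
        if self.height < 8 or self.width < 8:
            raise ValueError(f"height/width: scene must be at least 8x8, got "
                             f"{self.height}x{self.width}")
        if self.noise_sigma < 0:
            raise ValueError(f"noise_sigma: must be >= 0, got {self.noise_sigma}")
        max_r = self.blobs.radius_range[1]
        if self.blobs.count > 0 and 2 * (max_r + 2) >= min(self.height, self.width) // 2:
            raise ValueError("blobs.radius_range: blobs too large for the scene")


@dataclass(frozen=True)
class BlobTruth:
    blob_id: int
    centroid_x: float
    centroid_y: float
    n_pixels: int
    radius: int


@dataclass(frozen=True)
class SceneTruth:
    """Ground truth: per-frame union masks and per-blob records."""

    masks: tuple[np.ndarray, ...]
    blobs: tuple[tuple[BlobTruth, ...], ...]  # blobs[t] = records of frame t

    @property
    def counts(self) -> tuple[int, ...]:
        return tuple(len(b) for b in self.blobs)


def _disk_mask(h: int, w: int, cx: float, cy: float, r: int) -> np.ndarray:
    yy, xx = np.ogrid[:h, :w]
    return (xx - cx) ** 2 + (yy - cy) ** 2 <= r * r


def _texture(shape: tuple[int, int], rng: np.random.Generator, cfg: BackgroundConfig) -> np.ndarray:
    raw = rng.standard_normal(shape)
    tex = gaussian_filter(raw, cfg.texture_scale, mode="wrap")
    peak = np.max(np.abs(tex)) or 1.0
    return tex * (cfg.texture_contrast / peak)


class _BlobState:
    def __init__(self, blob_id: int, cfg: SceneConfig, rng: np.random.Generator):
        b = cfg.blobs
        self.blob_id = blob_id
        self.rng = rng
        self.radius = int(rng.integers(b.radius_range[0], b.radius_range[1] + 1))
        self.offset = float(rng.uniform(*b.offset_range))
        self.d_lo, self.d_hi = b.displacement_bounds(self.radius)
        margin = self.radius + 1
        self.x = float(rng.uniform(margin, cfg.width - 1 - margin))
        self.y = float(rng.uniform(margin, cfg.height - 1 - margin))
        self.h, self.w = cfg.height, cfg.width
        self.margin = margin

    def step(self) -> None:
        # rejection-sample a direction that keeps the full displacement in
        # bounds: reflecting a step would shorten it and could break the
        # non-overlap premise near walls
        d = float(self.rng.uniform(self.d_lo, self.d_hi))
        for _ in range(256):
            theta = float(self.rng.uniform(0.0, 2.0 * np.pi))
            nx = self.x + d * np.cos(theta)
            ny = self.y + d * np.sin(theta)
            if self.margin <= nx <= self.w - 1 - self.margin and (
                self.margin <= ny <= self.h - 1 - self.margin
            ):
                self.x, self.y = nx, ny
                return
        raise RuntimeError("could not place blob step inside the scene")


def generate_scene(cfg: SceneConfig = SceneConfig()) -> tuple[list[GrayFrame], SceneTruth]:
    """Render the scene and its exact ground truth.

    Layer order per frame: background → blob offsets (added on the disk
    pixels) → sediment cloud → Gaussian noise → clip to [0, 255].  Identical
    config (including seed) ⇒ bit-identical frames and truth.
    """
    ss = np.random.SeedSequence(cfg.seed)
    bg_ss, sed_ss, noise_ss, *blob_ss = ss.spawn(3 + cfg.blobs.count)
    bg_rng = np.random.default_rng(bg_ss)
    noise_rng = np.random.default_rng(noise_ss)
    sed_rng = np.random.default_rng(sed_ss)

    shape = (cfg.height, cfg.width)
    bg_cfg = cfg.background
    if bg_cfg.mode == "constant":
        base = np.full(shape, bg_cfg.level)
        def background(t: int) -> np.ndarray:
            return base
    else:
        tex = bg_cfg.level + _texture(shape, bg_rng, bg_cfg)
        if bg_cfg.mode == "texture":
            def background(t: int) -> np.ndarray:
                return tex
        else:
            vx, vy = bg_cfg.drift_velocity
            def background(t: int) -> np.ndarray:
                return np.roll(tex, (round(vy * t), round(vx * t)), axis=(0, 1))

    if cfg.sediment.enabled:
        sx0 = sed_rng.uniform(0.25, 0.75) * cfg.width
        sy0 = sed_rng.uniform(0.25, 0.75) * cfg.height
        yy, xx = np.mgrid[: cfg.height, : cfg.width]

        def sediment(t: int) -> np.ndarray:
            cx = sx0 + cfg.sediment.velocity[0] * t
            cy = sy0 + cfg.sediment.velocity[1] * t
            env = np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * cfg.sediment.extent**2))
            return cfg.sediment.contrast * env
    else:
        def sediment(t: int) -> np.ndarray:
            return 0.0

    blobs = [_BlobState(i, cfg, np.random.default_rng(s)) for i, s in enumerate(blob_ss)]

    frames: list[GrayFrame] = []
    masks: list[np.ndarray] = []
    records: list[tuple[BlobTruth, ...]] = []
    for t in range(cfg.n_frames):
        if t > 0:
            for blob in blobs:
                blob.step()
        img = np.array(background(t), dtype=np.float64, copy=True) + sediment(t)
        union = np.zeros(shape, dtype=bool)
        recs = []
        for blob in blobs:
            m = _disk_mask(cfg.height, cfg.width, blob.x, blob.y, blob.radius)
            bump = blob.offset * m
            if cfg.blobs.soft_edge_sigma > 0:
                bump = gaussian_filter(bump, cfg.blobs.soft_edge_sigma)
                m = bump > 1e-9
            img += bump
            union |= m
            ys, xs = np.nonzero(m)
            recs.append(
                BlobTruth(
                    blob_id=blob.blob_id,
                    centroid_x=float(xs.mean()) if xs.size else float(blob.x),
                    centroid_y=float(ys.mean()) if ys.size else float(blob.y),
                    n_pixels=int(m.sum()),
                    radius=blob.radius,
                )
            )
        if cfg.noise_sigma > 0:
            img = img + noise_rng.normal(0.0, cfg.noise_sigma, shape)
        img = np.clip(img, 0.0, 255.0)
        frames.append(GrayFrame(img, index=t))
        masks.append(union)
        records.append(tuple(recs))
    return frames, SceneTruth(masks=tuple(masks), blobs=tuple(records))


_TRIPLE_KINDS = ("fast_blob", "slow_blob", "static", "sediment_only")


def generate_triple(kind: str, seed: int = 0) -> tuple[FrameTriple, SceneTruth]:
    """A three-frame fixture scene of the given kind.

    ``fast_blob`` satisfies the opposition premises exactly (constant
    background, zero noise, displacement > diameter); ``slow_blob`` violates
    the non-overlap premise; ``static`` has no motion at all;
    ``sediment_only`` contains only the diffuse distractor.
    """
    if kind not in _TRIPLE_KINDS:
        raise ValueError(f"unknown triple kind {kind!r}; expected one of {_TRIPLE_KINDS}")
    base = dict(n_frames=3, height=48, width=48, noise_sigma=0.0, seed=seed)
    if kind == "fast_blob":
        cfg = SceneConfig(blobs=BlobConfig(count=1, radius_range=(3, 3)), **base)
    elif kind == "slow_blob":
        cfg = SceneConfig(
            blobs=BlobConfig(count=1, radius_range=(3, 3), fast=False,
                             displacement_range=(2.0, 2.0)),
            **base,
        )
    elif kind == "static":
        cfg = SceneConfig(
            background=BackgroundConfig(mode="texture"),
            blobs=BlobConfig(count=0),
            **base,
        )
    else:  # sediment_only
        cfg = SceneConfig(
            blobs=BlobConfig(count=0),
            sediment=SedimentConfig(enabled=True),
            **base,
        )
    frames, truth = generate_scene(cfg)
    return FrameTriple(prev=frames[0], mid=frames[1], next=frames[2]), truth
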