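"""Spatiotemporal gradients and the Horn–Schunck relaxation.

The gradients are the 2×2×2-kernel first differences of a frame pair

    ∇t(x,y) = ½[(b−a)(x,y)   + (b−a)(x+1,y)]
    ∇x(x,y) = ½[(b(x+1,y)−b(x,y)) + (a(x+1,y)−a(x,y))]
    ∇y(x,y) = ½[(b(x,y+1)−b(x,y)) + (a(x,y+1)−a(x,y))]

evaluated on the edge-replicated padded block, and the flow field is obtained
by relaxing the brightness-constancy residual from u₀ = v₀ = 0:

    Δ = (∇x·u + ∇y·v + ∇t) / (α² + ∇x² + ∇y²),   u ← u − ∇x·Δ,   v ← v − ∇y·Δ.

The update is applied pointwise (each pixel uses its *own* current (u,v));
the classic solver's 3×3 neighborhood mean is available via
``neighborhood_average`` but is off by default, because the opposite-flow
detection property is exact only for the pointwise form.  Everything in this
module is deterministic: identical inputs give bit-identical outputs.

The key property this module exists for: for a small object whose positions
in frames t−1, t, t+1 do not overlap, over a locally time-invariant
background, the two consecutive flow fields are exact negatives of each other
at the object's middle-frame position (u = −u′, v = −v′).  The proof is an
induction over iterations: ∇t′ = −∇t, ∇x′ = ∇x, ∇y′ = ∇y there, so each
iteration preserves the sign flip.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import convolve, uniform_filter

from .frames import FrameTriple, GrayFrame, pad_pair

__all__ = [
    "GradientField",
    "FlowField",
    "FlowPair",
    "compute_gradients",
    "hs_solve",
    "flow_pair",
    "opposition_residual",
]


@dataclass(frozen=True)
class GradientField:
    """∇x, ∇y, ∇t of one frame pair, each shaped like the frame."""

    gx: np.ndarray
    gy: np.ndarray
    gt: np.ndarray

    def __post_init__(self) -> None:
        if not (self.gx.shape == self.gy.shape == self.gt.shape):
            raise ValueError("gradient grids must share a shape")
        for g in (self.gx, self.gy, self.gt):
            if not np.all(np.isfinite(g)):
                raise ValueError("gradients must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.gx.shape


@dataclass(frozen=True)
class FlowField:
    """Dense flow (u horizontal, v vertical, pixels/frame) plus solver metadata."""

    u: np.ndarray
    v: np.ndarray
    alpha2: float
    n_iters: int

    @property
    def shape(self) -> tuple[int, int]:
        return self.u.shape


@dataclass(frozen=True)
class FlowPair:
    """The two consecutive flow fields of a frame triple.

    ``first`` is the flow of frames t−1→t, ``second`` of t→t+1 (the primed
    field u′, v′ of the opposition property).
    """

    first: FlowField
    second: FlowField

    def __post_init__(self) -> None:
        if self.first.shape != self.second.shape:
            raise ValueError("flow pair fields must share a shape")
        if (self.first.alpha2, self.first.n_iters) != (self.second.alpha2, self.second.n_iters):
            raise ValueError("flow pair fields must share solver parameters")

    @property
    def shape(self) -> tuple[int, int]:
        return self.first.shape


def compute_gradients(a: GrayFrame, b: GrayFrame, cube_mean: bool = False) -> GradientField:
    """Spatiotemporal gradients of the pair a→b on the padded block.

    With ``cube_mean=True`` each gradient is instead averaged over the full
    2×2×2 cube (four first differences rather than two); the default two-term
    form is the one the detection theory is stated for.
    """
    block = pad_pair(a, b)
    h, w = a.shape
    A, B = block[:, :, 0], block[:, :, 1]
    a0, b0 = A[:h, :w], B[:h, :w]
    ax1, bx1 = A[:h, 1 : w + 1], B[:h, 1 : w + 1]
    ay1, by1 = A[1 : h + 1, :w], B[1 : h + 1, :w]
    if not cube_mean:
        gt = 0.5 * ((b0 - a0) + (bx1 - ax1))
        gx = 0.5 * ((bx1 - b0) + (ax1 - a0))
        gy = 0.5 * ((by1 - b0) + (ay1 - a0))
    else:
        axy1, bxy1 = A[1 : h + 1, 1 : w + 1], B[1 : h + 1, 1 : w + 1]
        gt = 0.25 * ((b0 - a0) + (bx1 - ax1) + (by1 - ay1) + (bxy1 - axy1))
        gx = 0.25 * ((bx1 - b0) + (ax1 - a0) + (bxy1 - by1) + (axy1 - ay1))
        gy = 0.25 * ((by1 - b0) + (ay1 - a0) + (bxy1 - bx1) + (axy1 - ax1))
    return GradientField(gx=gx, gy=gy, gt=gt)


_RING8 = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]], dtype=np.float64) / 8.0


def hs_solve(
    grad: GradientField,
    alpha2: float = 100.0,
    n_iters: int = 100,
    neighborhood_average: bool = False,
    include_center: bool = False,
) -> FlowField:
    """Relax the brightness-constancy residual to a dense flow field.

    Starting from u = v = 0, repeats ``n_iters`` times:
    Δ = (∇x·u + ∇y·v + ∇t)/(α² + ∇x² + ∇y²); u ← u − ∇x·Δ; v ← v − ∇y·Δ.
    α² > 0 keeps the denominator positive, so |Δ| ≤ (|∇x·u|+|∇y·v|+|∇t|)/α²
    and no iteration can produce non-finite values from finite gradients.

    ``neighborhood_average=True`` substitutes the 3×3 local mean of (u, v)
    into the update (the classic variational solver); ``include_center``
    selects whether that mean includes the pixel itself.
    """
    if alpha2 <= 0:
        raise ValueError(f"alpha2 must be > 0, got {alpha2}")
    if n_iters < 1:
        raise ValueError(f"n_iters must be >= 1, got {n_iters}")
    gx, gy, gt = grad.gx, grad.gy, grad.gt
    denom = alpha2 + gx * gx + gy * gy
    u = np.zeros_like(gx)
    v = np.zeros_like(gx)
    for _ in range(n_iters):
        if neighborhood_average:
            if include_center:
                ub = uniform_filter(u, size=3, mode="nearest")
                vb = uniform_filter(v, size=3, mode="nearest")
            else:
                ub = convolve(u, _RING8, mode="nearest")
                vb = convolve(v, _RING8, mode="nearest")
        else:
            ub, vb = u, v
        delta = (gx * ub + gy * vb + gt) / denom
        u = ub - gx * delta
        v = vb - gy * delta
    return FlowField(u=u, v=v, alpha2=float(alpha2), n_iters=int(n_iters))


def flow_pair(
    triple: FrameTriple,
    alpha2: float = 100.0,
    n_iters: int = 100,
    cube_mean: bool = False,
    neighborhood_average: bool = False,
    include_center: bool = False,
) -> FlowPair:
    """Both flow fields of a frame triple, solved with identical parameters."""
    kw = dict(
        alpha2=alpha2,
        n_iters=n_iters,
        neighborhood_average=neighborhood_average,
        include_center=include_center,
    )
    first = hs_solve(compute_gradients(triple.prev, triple.mid, cube_mean=cube_mean), **kw)
    second = hs_solve(compute_gradients(triple.mid, triple.next, cube_mean=cube_mean), **kw)
    return FlowPair(first=first, second=second)


def opposition_residual(pair: FlowPair, support: np.ndarray) -> tuple[float, float]:
    """(max|u+u′|, max|v+v′|) over the pixels of ``support``.

    The opposite-flow property holds exactly where the object sits in the
    *middle* frame (its t−1 and t+1 positions do not qualify: there one of
    the two flow fields vanishes while the other does not), so ``support``
    should be the middle-frame object mask (or any region where frames
    t−1 and t+1 agree on the whole gradient stencil).
    """
    support = np.asarray(support, dtype=bool)
    if support.shape != pair.shape:
        raise ValueError(f"support shape {support.shape} != flow shape {pair.shape}")
    if not support.any():
        return 0.0, 0.0
    du = np.abs(pair.first.u + pair.second.u)[support]
    dv = np.abs(pair.first.v + pair.second.v)[support]
    return float(du.max()), float(dv.max())
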