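"""Pressure-field inference from time-resolved 2D velocimetry.

The pressure gradient follows from the planar Navier-Stokes momentum
balance,

    grad p = -rho (du/dt + (u . grad) u) + mu laplacian(u),

evaluated with central differences (one-sided at domain edges and next to
masked nodes, so surface-contaminated vectors never enter a stencil). The
pressure itself is recovered by integrating the gradient along eight
straight rays (4 axis-aligned, 4 diagonal) running from the field-of-view
boundary to each node, and taking the median of the surviving ray
integrals. Rays crossing the body mask are excluded; the median makes the
result robust to locally corrupted gradients.

Ray anchoring: the pressure at the field-of-view edge, where rays start,
is itself obtained from the momentum data by integrating the tangential
pressure gradient around the closed boundary loop (the closure residual is
distributed uniformly in arc length). When the boundary truly sits in
quiescent far field this reduces to the conventional ambient gauge, which
is also available explicitly (``boundary="ambient"``); unlike the ambient
assumption it stays accurate when flow structures reach the edge of the
field of view. The final field is always shifted so the mean over unmasked
boundary nodes is zero (ambient gauge).

Viscous terms are retained in full, which matters at the appendage
Reynolds numbers (tens) this package targets.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import EmptyDomainError, InsufficientFramesError
from .fields import FluidProperties, GridGeometry, ScalarField, VelocityFieldSequence

#: ray directions (di, dj): 4 axis-aligned then 4 diagonal
DIRECTIONS = ((1, 0), (-1, 0), (0, 1), (0, -1), (1, 1), (1, -1), (-1, 1), (-1, -1))


@dataclass
class PressureGradientField:
    gx: np.ndarray              # (ny, nx), Pa/m
    gy: np.ndarray
    defined: np.ndarray         # False on masked/dilated and underivable nodes
    grid: GridGeometry


def _shift(a: np.ndarray, dj: int, di: int) -> np.ndarray:
    """out[j, i] = a[j - dj, i - di], NaN outside."""
    out = np.full_like(a, np.nan)
    ny, nx = a.shape
    jd = slice(max(dj, 0), ny + min(dj, 0))
    js = slice(max(-dj, 0), ny + min(-dj, 0))
    id_ = slice(max(di, 0), nx + min(di, 0))
    is_ = slice(max(-di, 0), nx + min(-di, 0))
    out[jd, id_] = a[js, is_]
    return out


def _d1(a: np.ndarray, h: float, axis: int) -> np.ndarray:
    """First derivative: central where both neighbors exist (are finite),
    else one-sided toward the available neighbor."""
    dj, di = (1, 0) if axis == 0 else (0, 1)
    ap = _shift(a, -dj, -di)    # a[j+dj, i+di]
    am = _shift(a, dj, di)      # a[j-dj, i-di]
    out = (ap - am) / (2 * h)
    fwd = (ap - a) / h
    bwd = (a - am) / h
    out = np.where(np.isnan(out), fwd, out)
    out = np.where(np.isnan(out), bwd, out)
    return out


def _d2(a: np.ndarray, h: float, axis: int) -> np.ndarray:
    """Second derivative: central 3-point where possible, else the
    one-sided 3-point stencil biased away from the unavailable side."""
    dj, di = (1, 0) if axis == 0 else (0, 1)
    ap = _shift(a, -dj, -di)
    am = _shift(a, dj, di)
    app = _shift(a, -2 * dj, -2 * di)
    amm = _shift(a, 2 * dj, 2 * di)
    out = (ap - 2 * a + am) / h**2
    fwd = (app - 2 * ap + a) / h**2
    bwd = (amm - 2 * am + a) / h**2
    out = np.where(np.isnan(out), fwd, out)
    out = np.where(np.isnan(out), bwd, out)
    return out


def pressure_gradient(
    seq: VelocityFieldSequence,
    frame: int,
    mask: np.ndarray | None = None,
    fluid: FluidProperties | None = None,
) -> PressureGradientField:
    """Momentum-balance pressure gradient at one frame.

    ``mask`` is the (already dilated) body raster; masked nodes and nodes
    whose every stencil fails are left undefined. The temporal derivative
    is central, one-sided at the first and last frame.
    """
    if seq.n_frames < 3:
        raise InsufficientFramesError("need at least 3 frames for temporal derivatives")
    if not 0 <= frame < seq.n_frames:
        raise InsufficientFramesError(f"frame {frame} outside sequence")
    fluid = fluid or FluidProperties.seawater()
    rho, mu = fluid.density, fluid.dynamic_viscosity
    excluded = ~seq.valid[frame]
    if mask is not None:
        excluded = excluded | np.asarray(mask, dtype=bool)

    def masked(t: int) -> tuple[np.ndarray, np.ndarray]:
        bad = excluded | ~seq.valid[t]
        u = np.where(bad, np.nan, seq.u[t])
        v = np.where(bad, np.nan, seq.v[t])
        return u, v

    u, v = masked(frame)
    # temporal derivative (central; one-sided at sequence ends)
    t0, t1 = max(frame - 1, 0), min(frame + 1, seq.n_frames - 1)
    up, vp = masked(t1)
    um, vm = masked(t0)
    dt_span = (t1 - t0) * seq.dt
    du_dt = (up - um) / dt_span
    dv_dt = (vp - vm) / dt_span

    dx, dy = seq.grid.dx, seq.grid.dy
    du_dx, du_dy = _d1(u, dx, 1), _d1(u, dy, 0)
    dv_dx, dv_dy = _d1(v, dx, 1), _d1(v, dy, 0)
    lap_u = _d2(u, dx, 1) + _d2(u, dy, 0)
    lap_v = _d2(v, dx, 1) + _d2(v, dy, 0)

    gx = -rho * (du_dt + u * du_dx + v * du_dy) + mu * lap_u
    gy = -rho * (dv_dt + u * dv_dx + v * dv_dy) + mu * lap_v
    defined = np.isfinite(gx) & np.isfinite(gy) & ~excluded
    gx = np.where(defined, gx, np.nan)
    gy = np.where(defined, gy, np.nan)
    return PressureGradientField(gx=gx, gy=gy, defined=defined, grid=seq.grid)


def _segment_integrals(
    ge: np.ndarray, h: float, di: int, dj: int, n_sub: int
) -> np.ndarray:
    """Trapezoidal integral of the (bilinearly interpolated) directional
    gradient over the inter-node segment *ending* at each node, sampled at
    ``n_sub + 1`` points. NaN where any stencil value is undefined."""
    A = _shift(ge, dj, di)          # upstream node
    D = ge                          # this node
    if di != 0 and dj != 0:
        B = _shift(ge, 0, di)
        C = _shift(ge, dj, 0)
        f = np.linspace(0.0, 1.0, n_sub + 1)
        w = np.full(n_sub + 1, 1.0 / n_sub)
        w[0] = w[-1] = 0.5 / n_sub
        cA = float(np.sum(w * (1 - f) ** 2))
        cBC = float(np.sum(w * f * (1 - f)))
        cD = float(np.sum(w * f**2))
        return h * (cA * A + cBC * (B + C) + cD * D)
    # axis-aligned: interpolation along the ray is linear between nodes,
    # so the composite trapezoid is exact at any sub-sampling
    return h * 0.5 * (A + D)


def _ray_integrals(
    gx: np.ndarray, gy: np.ndarray, grid: GridGeometry, di: int, dj: int
) -> np.ndarray:
    """Line integral of grad p . dl from the boundary to each node along
    direction (di, dj). NaN where the ray crosses an undefined node."""
    dx, dy = grid.dx, grid.dy
    h = math.hypot(di * dx, dj * dy)
    ge = (gx * (di * dx) + gy * (dj * dy)) / h
    step = min(dx, dy)
    n_sub = max(1, math.ceil(h / step - 1e-9))
    seg = _segment_integrals(ge, h, di, dj, n_sub)
    ny, nx = ge.shape
    if dj == 0:
        s = seg.copy()
        if di == 1:
            s[:, 0] = 0.0
            return np.cumsum(s, axis=1)
        s[:, -1] = 0.0
        return np.cumsum(s[:, ::-1], axis=1)[:, ::-1]
    if di == 0:
        s = seg.copy()
        if dj == 1:
            s[0, :] = 0.0
            return np.cumsum(s, axis=0)
        s[-1, :] = 0.0
        return np.cumsum(s[::-1, :], axis=0)[::-1, :]
    # diagonal: sweep row by row
    out = np.zeros_like(ge)
    rows = range(1, ny) if dj == 1 else range(ny - 2, -1, -1)
    for j in rows:
        if di == 1:
            out[j, 1:] = out[j - dj, :-1] + seg[j, 1:]
            out[j, 0] = 0.0
        else:
            out[j, :-1] = out[j - dj, 1:] + seg[j, :-1]
            out[j, -1] = 0.0
    return out


def _boundary_loop_values(grad: PressureGradientField) -> np.ndarray:
    """Boundary pressures from the closed-loop integral of the tangential
    gradient around the field-of-view edge.

    The loop's closure residual (zero for an exact gradient field) is
    distributed uniformly in arc length. Segments with undefined gradient
    carry the value across unchanged (those boundary nodes only anchor
    rays that are blocked anyway). Zero-mean over the boundary.
    """
    g = grad.grid
    ny, nx = g.shape
    js = np.concatenate(
        [
            np.zeros(nx - 1, dtype=int),
            np.arange(0, ny - 1),
            np.full(nx - 1, ny - 1),
            np.arange(ny - 1, 0, -1),
        ]
    )
    is_ = np.concatenate(
        [
            np.arange(0, nx - 1),
            np.full(ny - 1, nx - 1),
            np.arange(nx - 1, 0, -1),
            np.zeros(ny - 1, dtype=int),
        ]
    )
    jn, in_ = np.roll(js, -1), np.roll(is_, -1)
    ddx = (in_ - is_).astype(float) * g.dx
    ddy = (jn - js).astype(float) * g.dy
    seg = 0.5 * (
        (grad.gx[js, is_] + grad.gx[jn, in_]) * ddx
        + (grad.gy[js, is_] + grad.gy[jn, in_]) * ddy
    )
    seg = np.nan_to_num(seg)
    vals = np.concatenate([[0.0], np.cumsum(seg)])
    s = np.concatenate([[0.0], np.cumsum(np.hypot(ddx, ddy))])
    vals = vals[:-1] - vals[-1] * s[:-1] / s[-1]
    out = np.zeros(g.shape)
    out[js, is_] = vals
    out -= out[g.boundary_mask()].mean()
    return out


def _chain_start_values(pb: np.ndarray, di: int, dj: int) -> np.ndarray:
    """Value of ``pb`` at the boundary node where the (di, dj) ray of each
    node starts."""
    ny, nx = pb.shape
    if dj == 0:
        col = pb[:, 0] if di == 1 else pb[:, -1]
        return np.repeat(col[:, None], nx, axis=1)
    if di == 0:
        row = pb[0, :] if dj == 1 else pb[-1, :]
        return np.repeat(row[None, :], ny, axis=0)
    out = np.array(pb)
    rows = range(1, ny) if dj == 1 else range(ny - 2, -1, -1)
    for j in rows:
        if di == 1:
            out[j, 1:] = out[j - dj, :-1]
        else:
            out[j, :-1] = out[j - dj, 1:]
    return out


def integrate_eight_paths(
    grad: PressureGradientField,
    boundary: str = "loop",
    return_diagnostics: bool = False,
):
    """Median-of-eight-rays pressure reconstruction.

    Each unmasked node casts 8 straight rays to the field-of-view boundary.
    With ``boundary="loop"`` (default) each ray is anchored at the boundary
    pressure from :func:`_boundary_loop_values`; ``boundary="ambient"``
    anchors every ray at zero (valid when the field of view extends into
    quiescent fluid). Rays intersecting the undefined (masked) region are
    excluded; node pressure is the median of the surviving ray integrals
    (mean of the central two for an even count). Nodes with no surviving
    ray stay undefined. Finally the field is shifted so the mean over
    defined boundary nodes is zero.
    """
    if not grad.defined.any():
        raise EmptyDomainError("entire field is masked")
    if boundary not in ("loop", "ambient"):
        raise EmptyDomainError(f"unknown boundary mode '{boundary}'")
    pb = (
        _boundary_loop_values(grad)
        if boundary == "loop"
        else np.zeros(grad.grid.shape)
    )
    rays = np.stack(
        [
            _chain_start_values(pb, di, dj)
            + _ray_integrals(grad.gx, grad.gy, grad.grid, di, dj)
            for di, dj in DIRECTIONS
        ]
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        p = np.nanmedian(rays, axis=0)
    n_surviving = np.sum(np.isfinite(rays), axis=0)
    p = np.where(grad.defined & (n_surviving > 0), p, np.nan)
    boundary = grad.grid.boundary_mask() & np.isfinite(p)
    if not boundary.any():
        raise EmptyDomainError("no defined boundary node to fix the pressure gauge")
    p = p - p[boundary].mean()
    field = ScalarField(values=p, grid=grad.grid, units="Pa")
    if return_diagnostics:
        return field, n_surviving
    return field


def compute_pressure_sequence(
    seq: VelocityFieldSequence,
    masks: list[np.ndarray] | np.ndarray | None = None,
    fluid: FluidProperties | None = None,
    boundary: str = "loop",
) -> tuple[list[ScalarField], pd.DataFrame]:
    """Pressure field per frame plus per-frame diagnostics.

    ``masks`` may be a per-frame list of rasters, a single static raster,
    or None. Diagnostics: undefined-node count and the histogram of
    surviving-ray counts per frame.
    """
    fields: list[ScalarField] = []
    rows = []
    for t in range(seq.n_frames):
        if masks is None:
            m = None
        elif isinstance(masks, np.ndarray) and masks.ndim == 2:
            m = masks
        else:
            m = masks[t]
        grad = pressure_gradient(seq, t, mask=m, fluid=fluid)
        field, n_surv = integrate_eight_paths(grad, boundary=boundary, return_diagnostics=True)
        fields.append(field)
        hist = np.bincount(n_surv[grad.defined].ravel(), minlength=9)
        row = {"frame": t, "undefined_nodes": int((~field.defined).sum())}
        row.update({f"rays_{k}": int(hist[k]) for k in range(9)})
        rows.append(row)
    return fields, pd.DataFrame(rows)
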