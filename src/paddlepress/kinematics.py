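"""Propulsor bending kinematics.

A propulsor (limb, ctene) digitized as a base-to-tip polyline is reduced to
two numbers per frame: the *bend angle* between the proximal and distal
parts, and the *inflexion fraction* -- the arc-length position of the bend
as a fraction of propulsor length. Both come from a two-segment
piecewise-linear least-squares fit with the vertex constrained to lie on
the centerline, the minimal model consistent with reporting a single angle
and a single inflexion point.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateInputError, InvalidParameterError, InvalidWindowError

# Breakpoint search window (arc-length fraction): fits with too few points
# per segment are ill-posed.
SEARCH_RANGE = (0.2, 0.9)
# Single-line RMS residual below this fraction of L declares "straight".
COLLINEAR_TOL = 0.005


@dataclass
class Centerline:
    """Base-to-tip polyline with equal arc-length spacing (meters)."""

    points: np.ndarray          # (n, 2)
    arc_length: np.ndarray      # (n,), cumulative, starts at 0
    L: float                    # total length

    @property
    def fractions(self) -> np.ndarray:
        return self.arc_length / self.L


@dataclass
class BendFit:
    bend_angle: float           # degrees, in [0, 180)
    inflexion_fraction: float   # in (0, 1)
    fit_residual: float         # RMS perpendicular residual, meters
    reliable: bool = True       # False for (near-)straight centerlines


@dataclass
class PropulsorSummary:
    """Mid-power-stroke kinematics of one propulsor."""

    bend_angle: float
    inflexion_fraction: float
    tip_speed: float
    reynolds: float


def resample_centerline(polyline: np.ndarray, n_points: int = 51) -> Centerline:
    """Resample a base-to-tip polyline to equal arc-length spacing.

    Duplicate consecutive points are removed; total length is preserved
    (linear interpolation along the original chords).
    """
    pts = np.atleast_2d(np.asarray(polyline, dtype=float))
    if n_points < 5:
        raise InvalidParameterError("n_points must be >= 5")
    keep = np.ones(len(pts), dtype=bool)
    keep[1:] = np.linalg.norm(np.diff(pts, axis=0), axis=1) > 0
    pts = pts[keep]
    if len(pts) < 2:
        raise DegenerateInputError("polyline has fewer than 2 distinct points")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    L = float(s[-1])
    if L <= 0:
        raise DegenerateInputError("zero-length polyline")
    s_new = np.linspace(0.0, L, n_points)
    x = np.interp(s_new, s, pts[:, 0])
    y = np.interp(s_new, s, pts[:, 1])
    out = np.column_stack([x, y])
    # arc coordinate measured along the original polyline: exactly equal
    # spacing and exact total length
    return Centerline(points=out, arc_length=s_new, L=L)


def _principal_direction(deltas: np.ndarray) -> tuple[np.ndarray, float]:
    """Best-fit line direction through the origin for offset vectors
    ``deltas`` (total least squares); returns (unit direction, sum of
    squared perpendicular residuals)."""
    m = deltas.T @ deltas
    w, vec = np.linalg.eigh(m)
    d = vec[:, -1]
    resid = float(w[0])
    return d, resid


def _tls_line(points: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Total-least-squares line through a point set: (centroid, unit
    direction, sum of squared perpendicular residuals)."""
    c = points.mean(axis=0)
    d, resid = _principal_direction(points - c)
    return c, d, resid


def _arc_position(pts: np.ndarray, arc: np.ndarray, point: np.ndarray) -> float:
    """Arc-length coordinate of the closest point on the polyline."""
    a, b = pts[:-1], pts[1:]
    ab = b - a
    lens2 = np.einsum("ij,ij->i", ab, ab)
    t = np.clip(np.einsum("ij,ij->i", point - a, ab) / np.maximum(lens2, 1e-300), 0, 1)
    proj = a + t[:, None] * ab
    d2 = np.einsum("ij,ij->i", point - proj, point - proj)
    k = int(np.argmin(d2))
    return float(arc[k] + t[k] * np.sqrt(lens2[k]))


def fit_bend(
    centerline: Centerline,
    search_range: tuple[float, float] = SEARCH_RANGE,
    base_first: bool = True,
) -> BendFit:
    """Two-segment piecewise-linear fit of a resampled centerline.

    The breakpoint is searched exhaustively over interior nodes whose arc
    fraction lies in ``search_range``: each candidate splits the points
    into proximal and distal sets (sharing the breakpoint node), each set
    gets a free total-least-squares line, and the candidate minimizing the
    total squared perpendicular residual wins (ties toward the smaller
    fraction). Continuity is enforced by placing the vertex at the
    intersection of the two fitted lines, so a noiseless two-segment
    polyline is recovered exactly even when its corner falls between
    nodes. The bend angle is the angle between the base->tip oriented
    segment directions; the inflexion fraction is the vertex's arc-length
    position on the centerline over its total length.

    A centerline collinear within tolerance returns bend_angle 0 with the
    inflexion fraction flagged unreliable rather than raising.
    """
    pts = centerline.points if base_first else centerline.points[::-1]
    n = len(pts)
    L = centerline.L
    # collinearity check: single TLS line through the centroid
    _, straight_resid = _principal_direction(pts - pts.mean(axis=0))
    if np.sqrt(straight_resid / n) < COLLINEAR_TOL * L:
        return BendFit(
            bend_angle=0.0,
            inflexion_fraction=0.5,
            fit_residual=float(np.sqrt(straight_resid / n)),
            reliable=False,
        )
    arc = centerline.arc_length
    frac = arc / L
    if not base_first:
        frac = 1.0 - frac[::-1]
        arc = frac * L
    lo, hi = search_range
    candidates = [
        b for b in range(1, n - 1) if lo - 1e-12 <= frac[b] <= hi + 1e-12
    ]
    if not candidates:
        raise InvalidParameterError("no interior breakpoint candidates in search range")
    best = None
    for b in candidates:
        c1, d1, r1 = _tls_line(pts[: b + 1])
        c2, d2, r2 = _tls_line(pts[b:])
        total = r1 + r2
        if best is None or total < best[0] - 1e-18:
            best = (total, b, c1, d1, c2, d2)
    total, b, c1, d1, c2, d2 = best
    # orient directions base -> tip
    if d1 @ (pts[b] - pts[0]) < 0:
        d1 = -d1
    if d2 @ (pts[-1] - pts[b]) < 0:
        d2 = -d2
    angle = float(np.degrees(np.arccos(np.clip(d1 @ d2, -1.0, 1.0))))
    cross = d1[0] * d2[1] - d1[1] * d2[0]
    if abs(cross) > 1e-9:
        # vertex = intersection of the two lines (continuity constraint)
        rhs = c2 - c1
        t1 = (rhs[0] * d2[1] - rhs[1] * d2[0]) / cross
        vertex = c1 + t1 * d1
        s_v = _arc_position(pts, arc, vertex)
    else:
        s_v = float(arc[b])
    fraction = min(max(s_v / L, 1e-9), 1 - 1e-9)
    return BendFit(
        bend_angle=angle,
        inflexion_fraction=float(fraction),
        fit_residual=float(np.sqrt(max(total, 0.0) / n)),
        reliable=True,
    )


def select_mid_power_stroke(stroke_frames: tuple[int, int]) -> int:
    """Frame at the temporal midpoint of the power stroke (inclusive
    window); ties break toward the earlier frame."""
    start, end = stroke_frames
    if end < start:
        raise InvalidWindowError(f"empty stroke window ({start}, {end})")
    return (start + end) // 2


def detect_power_stroke(tip_angles: np.ndarray) -> tuple[int, int]:
    """Longest run of monotone tip-angle change, taken as the power stroke.

    ``tip_angles`` is the base-to-tip orientation angle per frame
    (radians or degrees; only sign changes of its increments matter).
    """
    ang = np.asarray(tip_angles, dtype=float)
    if len(ang) < 2:
        raise InvalidWindowError("need at least 2 frames to detect a stroke")
    sign = np.sign(np.diff(ang))
    best = (0, 0)
    start = 0
    for k in range(1, len(sign) + 1):
        if k == len(sign) or sign[k] != sign[start] or sign[k] == 0:
            if sign[start] != 0 and (k - start) > (best[1] - best[0]):
                best = (start, k)
            start = k
    if best == (0, 0):
        return (0, len(ang) - 1)
    return best


def compute_reynolds(speed: float, length: float, kinematic_viscosity: float) -> float:
    """Appendage Reynolds number Re = U L / nu."""
    if speed <= 0 or length <= 0 or kinematic_viscosity <= 0:
        raise InvalidParameterError("speed, length and viscosity must be positive")
    return speed * length / kinematic_viscosity


def tip_speed(centerlines: list[Centerline], dt: float, frame: int) -> float:
    """Tip speed at ``frame`` by central differencing of tip positions."""
    tips = np.array([c.points[-1] for c in centerlines])
    t0 = max(frame - 1, 0)
    t1 = min(frame + 1, len(tips) - 1)
    if t1 == t0:
        raise InvalidWindowError("need at least 2 frames for tip speed")
    return float(np.linalg.norm(tips[t1] - tips[t0]) / ((t1 - t0) * dt))
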