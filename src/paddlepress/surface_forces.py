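"""Surface force and torque from pressure, and pull/push thrust decomposition.

The body outline is divided into segments of equal arc length; the force
per unit depth is the pressure integral

    F = sum_i ( -p_i n_i ) ds        [N/m]

with n_i the outward unit normal of segment i. Because pressure is
undefined inside the dilated body mask, each segment samples the field a
small distance *outside* the surface along its normal (the probe offset).

Thrust decomposition: with a the unit swimming direction, segment i
contributes t_i = (-p_i n_i ds) . a; *pull* sums the contributions of
negative-pressure segments, *push* those of positive-pressure segments,
so total = pull + push exactly. Suction thrust shows up as pull-dominated
totals (stroke-averaged |pull|/|push| ratio above 1).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import LinearRing, LineString

from .errors import (
    AlignmentError,
    InvalidAxisError,
    InvalidContourError,
    InvalidWindowError,
    UnreliableSamplingError,
)
from .fields import ScalarField, bilinear_sample


@dataclass
class SurfaceContour:
    """Equal-arc-length segmented surface with outward unit normals."""

    midpoints: np.ndarray       # (n, 2) m
    normals: np.ndarray         # (n, 2) unit outward
    ds: float                   # segment length, m (equal across segments)
    closed: bool
    vertices: np.ndarray        # (n+1, 2) resampled vertices (closed: wraps)

    @property
    def n_segments(self) -> int:
        return len(self.midpoints)

    @property
    def perimeter(self) -> float:
        return self.ds * self.n_segments


@dataclass
class StrokeForceSeries:
    """Per-frame pull/push/total thrust-axis force per unit depth."""

    frames: np.ndarray
    times: np.ndarray
    pull: np.ndarray            # N/m, signed thrust-axis component
    push: np.ndarray
    total: np.ndarray
    thrust_axis: np.ndarray
    pull_push_ratio: float      # |mean pull| / |mean push| over the window; NaN if mean push is 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": self.frames,
                "time_s": self.times,
                "pull_N_per_m": self.pull,
                "push_N_per_m": self.push,
                "total_N_per_m": self.total,
            }
        )


def _resample_closed(pts: np.ndarray, n: int) -> np.ndarray:
    closed_pts = np.vstack([pts, pts[:1]])
    seg = np.linalg.norm(np.diff(closed_pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    s_new = np.linspace(0.0, total, n + 1)
    x = np.interp(s_new, s, closed_pts[:, 0])
    y = np.interp(s_new, s, closed_pts[:, 1])
    return np.column_stack([x, y])


def _resample_open(pts: np.ndarray, n: int) -> np.ndarray:
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    s_new = np.linspace(0.0, s[-1], n + 1)
    x = np.interp(s_new, s, pts[:, 0])
    y = np.interp(s_new, s, pts[:, 1])
    return np.column_stack([x, y])


def make_surface(
    contour_points: np.ndarray,
    n_segments: int = 64,
    closed: bool = True,
    leeward_point: np.ndarray | None = None,
) -> SurfaceContour:
    """Equal-arc-length segmentation with outward normals.

    Closed contours orient normals away from the polygon interior
    (independent of input winding). Open surfaces need ``leeward_point``;
    normals are oriented away from it.
    """
    pts = np.asarray(contour_points, dtype=float)
    minimum = 8 if closed else 4
    if n_segments < minimum:
        raise InvalidContourError(f"need at least {minimum} segments")
    if closed:
        if len(pts) < 3:
            raise InvalidContourError("closed contour needs >= 3 points")
        if not LinearRing(pts).is_simple:
            raise InvalidContourError("self-intersecting contour")
        verts = _resample_closed(pts, n_segments)
    else:
        if len(pts) < 2:
            raise InvalidContourError("open surface needs >= 2 points")
        if not LineString(pts).is_simple:
            raise InvalidContourError("self-intersecting polyline")
        verts = _resample_open(pts, n_segments)
    deltas = np.diff(verts, axis=0)
    lens = np.linalg.norm(deltas, axis=1)
    if lens.min() <= 0:
        raise InvalidContourError("degenerate contour: zero-length segment")
    # ds is the arc length of each segment, exactly equal by construction;
    # chord lengths differ from it only at sharp corners
    if closed:
        closed_pts = np.vstack([pts, pts[:1]])
        total = float(np.linalg.norm(np.diff(closed_pts, axis=0), axis=1).sum())
    else:
        total = float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())
    ds = total / n_segments
    tangents = deltas / lens[:, None]
    normals = np.column_stack([tangents[:, 1], -tangents[:, 0]])  # tangent rotated -90 deg
    mids = 0.5 * (verts[:-1] + verts[1:])
    if closed:
        # signed area > 0 means counterclockwise, for which the -90 deg
        # rotation already points outward
        x, y = verts[:-1, 0], verts[:-1, 1]
        area = 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
        if area < 0:
            normals = -normals
    else:
        if leeward_point is None:
            raise InvalidContourError("open surface needs a leeward_point for orientation")
        away = mids - np.asarray(leeward_point, dtype=float)
        if np.sum(np.einsum("ij,ij->i", normals, away)) < 0:
            normals = -normals
    return SurfaceContour(midpoints=mids, normals=normals, ds=ds, closed=closed, vertices=verts)


def sample_surface_pressure(
    pressure: ScalarField,
    surface: SurfaceContour,
    probe_offset_cells: float = 2.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-segment surface pressure (Pa).

    Bilinear interpolation at ``midpoint + probe_offset_cells * min(dx, dy)
    * n``. Segments whose probe lands in the undefined region are flagged
    and inherit the nearest defined segment's value; more than 50%
    undefined raises."""
    off = probe_offset_cells * min(pressure.grid.dx, pressure.grid.dy)
    probes = surface.midpoints + off * surface.normals
    vals, ok = bilinear_sample(pressure.values, pressure.defined, pressure.grid, probes)
    flagged = ~ok
    if flagged.mean() > 0.5:
        raise UnreliableSamplingError(
            f"{int(flagged.sum())}/{len(flagged)} surface probes undefined"
        )
    if flagged.any():
        n = len(vals)
        good = np.flatnonzero(ok)
        for k in np.flatnonzero(flagged):
            if surface.closed:
                d = np.minimum((good - k) % n, (k - good) % n)
            else:
                d = np.abs(good - k)
            vals[k] = vals[good[np.argmin(d)]]
    return vals, flagged


def integrate_surface_force(pressures: np.ndarray, surface: SurfaceContour) -> np.ndarray:
    """F = sum(-p_i n_i) ds, newtons per meter of depth."""
    p = np.asarray(pressures, dtype=float)
    return -(surface.normals * p[:, None]).sum(axis=0) * surface.ds


def integrate_surface_torque(
    pressures: np.ndarray, surface: SurfaceContour, pivot: np.ndarray
) -> float:
    """tau = sum (r_i - pivot) x (-p_i n_i ds), counterclockwise positive."""
    p = np.asarray(pressures, dtype=float)
    r = surface.midpoints - np.asarray(pivot, dtype=float)
    f = -surface.normals * p[:, None] * surface.ds
    return float(np.sum(r[:, 0] * f[:, 1] - r[:, 1] * f[:, 0]))


def pull_push_decompose(
    pressures: np.ndarray,
    surface: SurfaceContour,
    thrust_axis: np.ndarray,
) -> tuple[float, float, float]:
    """(pull, push, total) thrust-axis forces (N/m).

    Pull sums contributions of segments at negative pressure, push those at
    positive pressure; zero-pressure segments contribute nothing, so
    total = pull + push exactly."""
    a = np.asarray(thrust_axis, dtype=float)
    if abs(1.0 - np.linalg.norm(a)) > 1e-6:
        raise InvalidAxisError("thrust axis must be a unit vector")
    p = np.asarray(pressures, dtype=float)
    t = -p * (surface.normals @ a) * surface.ds
    pull = float(t[p < 0].sum())
    push = float(t[p > 0].sum())
    return pull, push, pull + push


def stroke_series(
    pressure_fields: list[ScalarField],
    surfaces: list[SurfaceContour],
    thrust_axis: np.ndarray,
    window: tuple[int, int] | None = None,
    dt: float = 1.0,
    probe_offset_cells: float = 2.0,
) -> StrokeForceSeries:
    """Pull/push/total per frame over the power-stroke window, plus the
    stroke-averaged |pull|/|push| ratio (NaN when mean push is zero)."""
    if len(pressure_fields) != len(surfaces):
        raise AlignmentError(
            f"{len(pressure_fields)} pressure frames vs {len(surfaces)} surfaces"
        )
    n = len(pressure_fields)
    if window is None:
        window = (0, n - 1)
    start, end = window
    if not (0 <= start <= end < n):
        raise InvalidWindowError(f"window {window} outside sequence of {n} frames")
    frames = np.arange(start, end + 1)
    pulls, pushes, totals = [], [], []
    for t in frames:
        p_seg, _ = sample_surface_pressure(
            pressure_fields[t], surfaces[t], probe_offset_cells
        )
        pull, push, total = pull_push_decompose(p_seg, surfaces[t], thrust_axis)
        pulls.append(pull)
        pushes.append(push)
        totals.append(total)
    pulls = np.asarray(pulls)
    pushes = np.asarray(pushes)
    mean_push = pushes.mean()
    ratio = float(abs(pulls.mean()) / abs(mean_push)) if mean_push != 0 else float("nan")
    return StrokeForceSeries(
        frames=frames,
        times=frames * dt,
        pull=pulls,
        push=pushes,
        total=np.asarray(totals),
        thrust_axis=np.asarray(thrust_axis, dtype=float),
        pull_push_ratio=ratio,
    )
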