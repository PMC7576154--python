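"""Velocity and pressure profiles along the two sides of a propulsor.

Samples speed |u| (and optionally pressure) on two curves offset from the
propulsor centerline by a distance delta along the local normal. The
*flowward* side faces the paddle's motion during the power stroke; the
*leeward* side faces away from it. Derived metrics reproduce the standard
along-propulsor measurements: arc fraction of peak flow, leeward/flowward
mean-speed ratio, and the leeward-negative / flowward-positive pressure
asymmetry.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from shapely.geometry import LineString

from .errors import InvalidOffsetError, InvalidParameterError, UnreliableProfileError
from .fields import ScalarField, VelocityFieldSequence, bilinear_sample
from .kinematics import Centerline


@dataclass
class SideProfile:
    fractions: np.ndarray               # s/L in [0, 1], strictly increasing
    leeward_speed: np.ndarray           # m/s
    flowward_speed: np.ndarray
    offset: float                       # delta, m
    leeward_pressure: np.ndarray | None = None  # Pa
    flowward_pressure: np.ndarray | None = None


def _centerline_normals(points: np.ndarray, smooth: int = 7) -> np.ndarray:
    """Unit normals (tangent rotated +90 deg) at every centerline point.

    Tangents are central differences, averaged over a small window so the
    offset samples wrap smoothly around a sharp bend instead of folding."""
    t = np.gradient(points, axis=0)
    if smooth > 1 and len(points) > smooth:
        kernel = np.ones(smooth) / smooth
        t = np.column_stack(
            [np.convolve(t[:, k], kernel, mode="same") for k in range(2)]
        )
    t /= np.linalg.norm(t, axis=1)[:, None]
    return np.column_stack([-t[:, 1], t[:, 0]])


def offset_curves(
    centerline: Centerline,
    delta: float,
    motion_direction: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """(leeward, flowward) offset curves, each (n, 2).

    Each sample point is displaced +/- delta along the local normal; the
    flowward side is the one whose normal has positive dot product with
    the paddle's motion direction (evaluated at mid-arc). Raises if the
    offset makes a curve self-intersect.
    """
    if delta < 0:
        raise InvalidParameterError("offset delta must be >= 0")
    pts = centerline.points
    normals = _centerline_normals(pts)
    mid = len(pts) // 2
    d = np.asarray(motion_direction, dtype=float)
    side = np.sign(normals[mid] @ d)
    if side == 0:
        side = 1.0
    flowward = pts + side * delta * normals
    leeward = pts - side * delta * normals
    if delta > 0:
        # validity via the true geometric offset: it degenerates (splits or
        # self-intersects) exactly when delta exceeds what the centerline
        # geometry can support
        line = LineString(pts)
        for name, sign in (("leeward", -side), ("flowward", side)):
            off = line.offset_curve(sign * delta)
            if off.is_empty or off.geom_type != "LineString" or not off.is_simple:
                raise InvalidOffsetError(
                    f"offset {delta} makes the {name} curve self-intersect"
                )
    return leeward, flowward


def sample_profile(
    seq: VelocityFieldSequence,
    frame: int,
    curves: tuple[np.ndarray, np.ndarray],
    centerline: Centerline,
    pressure: ScalarField | None = None,
    max_undefined_frac: float = 0.25,
) -> SideProfile:
    """Bilinear samples of |u| (and pressure) along both offset curves."""
    leeward, flowward = curves
    speed = seq.speed(frame)
    defined = seq.valid[frame]
    lee_s, lee_ok = bilinear_sample(speed, defined, seq.grid, leeward)
    flo_s, flo_ok = bilinear_sample(speed, defined, seq.grid, flowward)
    for name, ok in (("leeward", lee_ok), ("flowward", flo_ok)):
        if (~ok).mean() > max_undefined_frac:
            raise UnreliableProfileError(
                f"more than {max_undefined_frac:.0%} of {name} speed samples undefined"
            )
    lee_p = flo_p = None
    if pressure is not None:
        lee_p, lee_pok = bilinear_sample(
            pressure.values, pressure.defined, pressure.grid, leeward
        )
        flo_p, flo_pok = bilinear_sample(
            pressure.values, pressure.defined, pressure.grid, flowward
        )
        for name, ok in (("leeward", lee_pok), ("flowward", flo_pok)):
            if (~ok).mean() > max_undefined_frac:
                raise UnreliableProfileError(
                    f"more than {max_undefined_frac:.0%} of {name} pressure samples undefined"
                )
    return SideProfile(
        fractions=centerline.fractions.copy(),
        leeward_speed=lee_s,
        flowward_speed=flo_s,
        offset=float(np.linalg.norm(leeward[0] - centerline.points[0])),
        leeward_pressure=lee_p,
        flowward_pressure=flo_p,
    )


def peak_flow_fraction(profile: SideProfile) -> float:
    """Arc fraction of the maximum speed over the union of both sides;
    ties break toward the smaller fraction. NaN flags an all-zero
    (quiescent) profile."""
    union = np.fmax(
        np.nan_to_num(profile.leeward_speed), np.nan_to_num(profile.flowward_speed)
    )
    if np.nanmax(union) <= 0:
        return float("nan")
    return float(profile.fractions[int(np.argmax(union))])


def side_velocity_ratio(profile: SideProfile) -> float:
    """Mean leeward speed / mean flowward speed; NaN when the flowward
    mean is zero."""
    lee = np.nanmean(profile.leeward_speed)
    flo = np.nanmean(profile.flowward_speed)
    if flo == 0 or np.isnan(flo):
        return float("nan")
    return float(lee / flo)


def pressure_asymmetry_ratio(profile: SideProfile) -> float:
    """|mean of negative leeward pressures| / mean of positive flowward
    pressures; samples failing the sign filter are excluded. NaN when no
    flowward sample is positive."""
    if profile.leeward_pressure is None or profile.flowward_pressure is None:
        raise InvalidParameterError("profile carries no pressure samples")
    lee = profile.leeward_pressure
    flo = profile.flowward_pressure
    lee_neg = lee[np.isfinite(lee) & (lee < 0)]
    flo_pos = flo[np.isfinite(flo) & (flo > 0)]
    if flo_pos.size == 0 or lee_neg.size == 0:
        return float("nan")
    return float(abs(lee_neg.mean()) / flo_pos.mean())


def vorticity(seq: VelocityFieldSequence, frame: int) -> np.ndarray:
    """Central-difference curl dv/dx - du/dy; a plotting aid only."""
    dv_dx = np.gradient(seq.v[frame], seq.grid.dx, axis=1)
    du_dy = np.gradient(seq.u[frame], seq.grid.dy, axis=0)
    return dv_dx - du_dy
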