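"""Analytic and semi-analytic benchmark scenes with known reference pressure.

No raw velocimetry of swimming animals is shipped with the package, so
every downstream stage is exercised on synthetic scenes:

* uniform flow (degenerate benchmark; pressure identically zero),
* a decaying vortex lattice (closed-form unsteady viscous solution of the
  Navier-Stokes equations; closed-form pressure),
* a Lamb-Oseen line vortex (pressure from the radial momentum balance,
  integrated by quadrature),
* a bending-paddle power stroke with a counter-rotating vortex pair
  anchored on the leeward side of the bend -- the flow topology measured
  around real limbs and ctenes. Its reference pressure comes from the
  pressure-Poisson solver (:mod:`paddlepress.poisson`), which is first
  validated against the lattice closed form.

All velocity fields with ``noise_sd=0`` are divergence-free *discretely*:
scenes built from a streamfunction sample it on a one-node-padded grid and
take central differences, which makes the central-difference divergence
vanish to round-off at every interior node.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import exp1
from shapely.geometry import LineString

from . import poisson
from .errors import InvalidParameterError
from .fields import FluidProperties, GridGeometry, ScalarField, VelocityFieldSequence
from .kinematics import Centerline, resample_centerline
from .masking import BodyMask, rasterize_mask, thicken_centerline
from .pressure import pressure_gradient

_EULER_GAMMA = 0.5772156649015329


@dataclass
class AnalyticScene:
    """A generated velocity sequence plus everything needed to grade the
    pipeline against it: reference pressure, and (when the scene has a
    body) centerlines and masks."""

    fields: VelocityFieldSequence
    reference_pressure: list[ScalarField]
    centerlines: list[Centerline] | None = None
    masks: list[BodyMask] | None = None
    params: dict = field(default_factory=dict)
    seed: int | None = None


def _grid(grid_shape: tuple[int, int], spacing: float) -> GridGeometry:
    ny, nx = grid_shape
    if nx < 2 or ny < 2:
        raise InvalidParameterError("grid dimensions must be >= 2")
    if spacing <= 0:
        raise InvalidParameterError("spacing must be positive")
    return GridGeometry(nx=nx, ny=ny, dx=spacing, dy=spacing)


def _zero_boundary_mean(p: np.ndarray, grid: GridGeometry) -> np.ndarray:
    return p - p[grid.boundary_mask()].mean()


# ---------------------------------------------------------------------------
# uniform flow


def make_uniform_flow(
    speed: float,
    grid_shape: tuple[int, int] = (64, 64),
    spacing: float = 1e-4,
    n_frames: int = 3,
    dt: float = 0.01,
    direction_deg: float = 0.0,
) -> AnalyticScene:
    """Steady uniform flow; reference pressure identically zero."""
    if n_frames < 3:
        raise InvalidParameterError("n_frames must be >= 3")
    if dt <= 0:
        raise InvalidParameterError("dt must be positive")
    if speed < 0:
        raise InvalidParameterError("speed must be >= 0")
    grid = _grid(grid_shape, spacing)
    ang = math.radians(direction_deg)
    u = np.full((n_frames, *grid.shape), speed * math.cos(ang))
    v = np.full((n_frames, *grid.shape), speed * math.sin(ang))
    seq = VelocityFieldSequence(u=u, v=v, grid=grid, dt=dt)
    ref = [
        ScalarField(values=np.zeros(grid.shape), grid=grid, units="Pa")
        for _ in range(n_frames)
    ]
    return AnalyticScene(
        fields=seq,
        reference_pressure=ref,
        params={
            "scene": "uniform",
            "speed": speed,
            "direction_deg": direction_deg,
            "spacing": spacing,
            "dt": dt,
            "n_frames": n_frames,
        },
    )


# ---------------------------------------------------------------------------
# decaying vortex lattice


def make_decaying_vortex_lattice(
    amplitude: float = 0.01,
    viscosity: float = 1.35e-6,
    wavenumber: float | None = None,
    grid_shape: tuple[int, int] = (128, 128),
    spacing: float = 1e-4,
    n_frames: int = 3,
    dt: float = 0.01,
    density: float = 1025.0,
) -> AnalyticScene:
    """Doubly periodic decaying vortex lattice with closed-form pressure.

        u =  U0 cos(kx) sin(ky) exp(-2 nu k^2 t)
        v = -U0 sin(kx) cos(ky) exp(-2 nu k^2 t)
        p = -(rho U0^2 / 4)(cos 2kx + cos 2ky) exp(-4 nu k^2 t)

    The default wavenumber fits exactly one wavelength across the domain;
    an explicit wavenumber must fit an integer number of wavelengths, so
    the zero-mean boundary gauge is well defined.
    """
    grid = _grid(grid_shape, spacing)
    span_x = (grid.nx - 1) * spacing
    span_y = (grid.ny - 1) * spacing
    if wavenumber is None:
        wavenumber = 2 * math.pi / span_x
    lam = 2 * math.pi / wavenumber
    for span in (span_x, span_y):
        ratio = span / lam
        if abs(ratio - round(ratio)) > 1e-6 or round(ratio) < 1:
            raise InvalidParameterError(
                "domain must span an integer number of wavelengths"
            )
    if n_frames < 3:
        raise InvalidParameterError("n_frames must be >= 3")
    if dt <= 0 or viscosity <= 0 or density <= 0:
        raise InvalidParameterError("dt, viscosity and density must be positive")
    k = wavenumber
    X, Y = grid.mesh()
    u = np.empty((n_frames, *grid.shape))
    v = np.empty((n_frames, *grid.shape))
    ref = []
    for t in range(n_frames):
        decay = math.exp(-2 * viscosity * k**2 * t * dt)
        u[t] = amplitude * np.cos(k * X) * np.sin(k * Y) * decay
        v[t] = -amplitude * np.sin(k * X) * np.cos(k * Y) * decay
        p = (
            -(density * amplitude**2 / 4)
            * (np.cos(2 * k * X) + np.cos(2 * k * Y))
            * decay**2
        )
        ref.append(
            ScalarField(values=_zero_boundary_mean(p, grid), grid=grid, units="Pa")
        )
    seq = VelocityFieldSequence(u=u, v=v, grid=grid, dt=dt)
    return AnalyticScene(
        fields=seq,
        reference_pressure=ref,
        params={
            "scene": "vortex_lattice",
            "amplitude": amplitude,
            "viscosity": viscosity,
            "wavenumber": k,
            "spacing": spacing,
            "dt": dt,
            "n_frames": n_frames,
            "density": density,
        },
    )


# ---------------------------------------------------------------------------
# Lamb-Oseen line vortex


def _lamb_oseen_psi(r2: np.ndarray, circulation: float, core_radius: float) -> np.ndarray:
    """Streamfunction of a Lamb-Oseen vortex; regular at the center where
    ln r^2 + E1(r^2/rc^2) -> ln rc^2 - gamma."""
    rc2 = core_radius**2
    out = np.empty_like(r2)
    tiny = r2 < 1e-24 * rc2
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.log(r2) + exp1(r2 / rc2)
    out = np.where(tiny, math.log(rc2) - _EULER_GAMMA, out)
    # exp1 underflows to 0 for large arguments, which is exact enough
    return -(circulation / (4 * math.pi)) * out


def lamb_oseen_speed(r: np.ndarray, circulation: float, core_radius: float) -> np.ndarray:
    """Azimuthal speed u_theta(r) = Gamma/(2 pi r) (1 - exp(-r^2/rc^2))."""
    r = np.asarray(r, dtype=float)
    out = np.zeros_like(r)
    nz = r > 0
    out[nz] = (
        circulation
        / (2 * math.pi * r[nz])
        * (1.0 - np.exp(-(r[nz] ** 2) / core_radius**2))
    )
    return out


def line_vortex_pressure_profile(
    r: np.ndarray,
    circulation: float,
    core_radius: float,
    density: float,
    r_ref: float,
    n_quad: int = 4000,
) -> np.ndarray:
    """p(r) from the radial momentum balance dp/dr = rho u_theta^2 / r,
    integrated numerically with p(r_ref) = 0 (trapezoidal quadrature on a
    dense radial grid). This is the reference-pressure oracle for the
    line-vortex scene."""
    r = np.asarray(r, dtype=float)
    rmax = max(float(r.max()), r_ref)
    rg = np.linspace(0.0, rmax, n_quad)
    integrand = np.zeros_like(rg)
    nz = rg > 0
    u = lamb_oseen_speed(rg[nz], circulation, core_radius)
    integrand[nz] = density * u**2 / rg[nz]
    from scipy.integrate import cumulative_trapezoid

    cumulative = np.concatenate([[0.0], cumulative_trapezoid(integrand, rg)])
    p_of_r = cumulative - np.interp(r_ref, rg, cumulative)
    return np.interp(r, rg, p_of_r)


def make_line_vortex(
    circulation: float,
    core_radius: float,
    center: tuple[float, float] | None = None,
    grid_shape: tuple[int, int] = (64, 64),
    spacing: float = 1e-4,
    density: float = 1025.0,
    n_frames: int = 3,
    dt: float = 0.01,
) -> AnalyticScene:
    """Steady Lamb-Oseen vortex (repeated over ``n_frames``).

    Velocity comes from central differences of the streamfunction on a
    padded grid (discretely divergence-free); reference pressure from the
    radial-momentum quadrature, gauged to zero mean on the boundary.
    """
    grid = _grid(grid_shape, spacing)
    if core_radius <= spacing:
        raise InvalidParameterError("core_radius must exceed the grid spacing")
    if n_frames < 3:
        raise InvalidParameterError("n_frames must be >= 3")
    if center is None:
        center = (
            grid.x0 + (grid.nx - 1) * spacing / 2,
            grid.y0 + (grid.ny - 1) * spacing / 2,
        )
    cx, cy = center
    if not (grid.x[0] <= cx <= grid.x[-1] and grid.y[0] <= cy <= grid.y[-1]):
        raise InvalidParameterError("vortex center must lie inside the grid")
    # streamfunction on a grid padded by one node, central differences
    xp = grid.x0 + spacing * np.arange(-1, grid.nx + 1)
    yp = grid.y0 + spacing * np.arange(-1, grid.ny + 1)
    XP, YP = np.meshgrid(xp, yp)
    r2 = (XP - cx) ** 2 + (YP - cy) ** 2
    if circulation == 0:
        u1 = np.zeros(grid.shape)
        v1 = np.zeros(grid.shape)
    else:
        psi = _lamb_oseen_psi(r2, circulation, core_radius)
        u1 = (psi[2:, 1:-1] - psi[:-2, 1:-1]) / (2 * spacing)
        v1 = -(psi[1:-1, 2:] - psi[1:-1, :-2]) / (2 * spacing)
    X, Y = grid.mesh()
    r = np.hypot(X - cx, Y - cy)
    p = line_vortex_pressure_profile(
        r.ravel(), circulation, core_radius, density, r_ref=float(r.max())
    ).reshape(grid.shape)
    p = _zero_boundary_mean(p, grid)
    u = np.repeat(u1[None], n_frames, axis=0)
    v = np.repeat(v1[None], n_frames, axis=0)
    seq = VelocityFieldSequence(u=u, v=v, grid=grid, dt=dt)
    ref = [ScalarField(values=p.copy(), grid=grid, units="Pa") for _ in range(n_frames)]
    return AnalyticScene(
        fields=seq,
        reference_pressure=ref,
        params={
            "scene": "line_vortex",
            "circulation": circulation,
            "core_radius": core_radius,
            "center": (cx, cy),
            "spacing": spacing,
            "density": density,
            "n_frames": n_frames,
            "dt": dt,
        },
    )


# ---------------------------------------------------------------------------
# bending paddle power stroke


def _rot(v: np.ndarray, deg: float) -> np.ndarray:
    a = math.radians(deg)
    c, s = math.cos(a), math.sin(a)
    return np.array([c * v[0] - s * v[1], s * v[0] + c * v[1]])


def make_paddle_scene(
    bend_angle: float = 27.0,
    inflexion_fraction: float = 0.59,
    paddle_length: float = 3e-3,
    stroke_amplitude: float = 40.0,
    n_frames: int = 9,
    dt: float = 6e-3,
    vortex_strength: float = 1.5e-4,
    noise_sd: float = 0.0,
    seed: int = 0,
    grid_shape: tuple[int, int] = (64, 64),
    spacing: float = 1e-4,
    density: float = 1025.0,
    viscosity: float = 1.35e-6,
    half_width: float | None = None,
    n_centerline_points: int = 101,
) -> AnalyticScene:
    """Bending paddle executing a power stroke, with a counter-rotating
    vortex pair anchored on the leeward side of the bend.

    The animal "swims up" (+y): the paddle hangs from its base, sweeps
    clockwise through ``stroke_amplitude`` degrees, and its distal part
    lags the motion by ``bend_angle`` with the bend at
    ``inflexion_fraction`` of the arc length. The velocity field is a
    paddle-motion-induced background plus the vortex pair (both built from
    a streamfunction, hence discretely divergence-free) plus optional
    Gaussian noise of sd ``noise_sd`` times the peak speed. Reference
    pressure comes from the pressure-Poisson solver applied to the
    noise-free field; masks are the thickened centerline rasterized with a
    one-cell dilation (the velocimetry-contamination guard).
    """
    if not 0 < inflexion_fraction < 1:
        raise InvalidParameterError("inflexion_fraction must lie in (0, 1)")
    if n_frames < 5:
        raise InvalidParameterError("n_frames must be >= 5")
    if paddle_length <= 0 or dt <= 0:
        raise InvalidParameterError("paddle_length and dt must be positive")
    grid = _grid(grid_shape, spacing)
    if half_width is None:
        half_width = 0.75 * spacing
    L = paddle_length
    base = np.array(
        [
            grid.x0 + 0.35 * (grid.nx - 1) * spacing,
            grid.y0 + 0.80 * (grid.ny - 1) * spacing,
        ]
    )
    theta0 = -40.0
    duration = (n_frames - 1) * dt
    theta_dot = (
        -math.radians(stroke_amplitude) / duration if stroke_amplitude else 0.0
    )  # rad/s, clockwise
    rng = np.random.default_rng(seed)

    xp = grid.x0 + spacing * np.arange(-1, grid.nx + 1)
    yp = grid.y0 + spacing * np.arange(-1, grid.ny + 1)
    XP, YP = np.meshgrid(xp, yp)

    centerlines: list[Centerline] = []
    masks: list[BodyMask] = []
    u = np.empty((n_frames, *grid.shape))
    v = np.empty((n_frames, *grid.shape))
    core_radius = 0.07 * L
    for t in range(n_frames):
        theta = theta0 - stroke_amplitude * (t / (n_frames - 1))
        e1 = np.array([math.cos(math.radians(theta)), math.sin(math.radians(theta))])
        e2 = _rot(e1, bend_angle)  # distal lags toward the leeward side
        lee = np.array([-e1[1], e1[0]])  # leeward unit normal (trailing side)
        bend_pt = base + inflexion_fraction * L * e1
        tip = bend_pt + (1 - inflexion_fraction) * L * e2
        centerlines.append(
            resample_centerline(np.array([base, bend_pt, tip]), n_centerline_points)
        )
        psi = np.zeros_like(XP)
        if vortex_strength:
            # counter-rotating pair anchored just off the leeward surface,
            # straddling the bend symmetrically along the bend bisector
            t_bis = _rot(e1, bend_angle / 2)
            n_bis = np.array([-t_bis[1], t_bis[0]])
            c1 = bend_pt + 0.09 * L * n_bis + 0.06 * L * t_bis
            c2 = bend_pt + 0.09 * L * n_bis - 0.06 * L * t_bis
            psi += _lamb_oseen_psi(
                (XP - c1[0]) ** 2 + (YP - c1[1]) ** 2, vortex_strength, core_radius
            )
            psi += _lamb_oseen_psi(
                (XP - c2[0]) ** 2 + (YP - c2[1]) ** 2, -vortex_strength, core_radius
            )
        if theta_dot:
            # weak entrained-fluid cell co-moving with the paddle
            u_bg = abs(theta_dot) * 0.1 * L
            motion = -lee
            sigma = 0.6 * L
            r2b = (XP - bend_pt[0]) ** 2 + (YP - bend_pt[1]) ** 2
            psi += (
                u_bg
                * (motion[0] * (YP - bend_pt[1]) - motion[1] * (XP - bend_pt[0]))
                * np.exp(-r2b / (2 * sigma**2))
            )
        u[t] = (psi[2:, 1:-1] - psi[:-2, 1:-1]) / (2 * spacing)
        v[t] = -(psi[1:-1, 2:] - psi[1:-1, :-2]) / (2 * spacing)
        outline = thicken_centerline(centerlines[-1].points, half_width)
        masks.append(rasterize_mask(outline, grid, dilation_cells=1))

    peak = float(np.hypot(u, v).max())
    fluid = FluidProperties.from_kinematic(density, viscosity)
    clean = VelocityFieldSequence(u=u.copy(), v=v.copy(), grid=grid, dt=dt)
    ref = []
    for t in range(n_frames):
        grad = pressure_gradient(clean, t, mask=None, fluid=fluid)
        ref.append(poisson.solve_pressure_poisson(grad.gx, grad.gy, grid))
    if noise_sd > 0 and peak > 0:
        u += rng.normal(0.0, noise_sd * peak, size=u.shape)
        v += rng.normal(0.0, noise_sd * peak, size=v.shape)
    seq = VelocityFieldSequence(u=u, v=v, grid=grid, dt=dt)
    return AnalyticScene(
        fields=seq,
        reference_pressure=ref,
        centerlines=centerlines,
        masks=masks,
        params={
            "scene": "paddle",
            "bend_angle": bend_angle,
            "inflexion_fraction": inflexion_fraction,
            "paddle_length": L,
            "stroke_amplitude": stroke_amplitude,
            "n_frames": n_frames,
            "dt": dt,
            "vortex_strength": vortex_strength,
            "noise_sd": noise_sd,
            "seed": seed,
            "spacing": spacing,
            "density": density,
            "viscosity": viscosity,
            "half_width": half_width,
            "base": tuple(base),
            "theta0_deg": theta0,
            "core_radius": core_radius,
        },
        seed=seed,
    )


def paddle_bend_point(scene: AnalyticScene, frame: int) -> np.ndarray:
    """Physical position of the bend at one frame (from the stored
    centerline and the scene's inflexion fraction)."""
    cl = scene.centerlines[frame]
    frac = scene.params["inflexion_fraction"]
    idx = int(np.argmin(np.abs(cl.fractions - frac)))
    return cl.points[idx]


def paddle_motion_direction(scene: AnalyticScene, frame: int) -> np.ndarray:
    """Unit direction of paddle motion at mid-arc for one frame."""
    cl = scene.centerlines[frame]
    mid = cl.points[len(cl.points) // 2]
    base = cl.points[0]
    r = mid - base
    # clockwise sweep: velocity of a material point is along (r_y, -r_x)
    m = np.array([r[1], -r[0]])
    n = np.linalg.norm(m)
    return m / n if n else np.array([1.0, 0.0])


# ---------------------------------------------------------------------------
# synthetic body images


def ellipse_contour(
    center: tuple[float, float], a: float, b: float, n_points: int = 256
) -> np.ndarray:
    """Closed ellipse contour (semi-axes a along x, b along y)."""
    t = np.linspace(0.0, 2 * math.pi, n_points, endpoint=False)
    return np.column_stack([center[0] + a * np.cos(t), center[1] + b * np.sin(t)])


def make_body_image(
    contour: np.ndarray,
    image_shape: tuple[int, int],
    body_level: float = 0.2,
    background_level: float = 0.8,
    noise_sd: float = 0.0,
    seed: int = 0,
    pixel_size: float = 1.0,
    supersample: int = 4,
) -> np.ndarray:
    """Anti-aliased dark body on a bright background, with additive
    Gaussian noise, clipped to [0, 1].

    ``contour`` is in physical coordinates (y up); ``pixel_size`` converts
    to pixels. Anti-aliasing renders the filled polygon at ``supersample``
    times the resolution and block-averages.
    """
    from skimage.draw import polygon2mask

    if body_level >= background_level:
        raise InvalidParameterError(
            "body_level must be below background_level (dark body on bright field)"
        )
    h, w = image_shape
    pts = np.asarray(contour, dtype=float)
    cols = pts[:, 0] / pixel_size
    rows = (h - 1) - pts[:, 1] / pixel_size
    if (
        cols.min() < -0.5
        or cols.max() > w - 0.5
        or rows.min() < -0.5
        or rows.max() > h - 0.5
    ):
        raise InvalidParameterError("contour exceeds image bounds")
    ss = int(supersample)
    poly = np.column_stack([(rows + 0.5) * ss - 0.5, (cols + 0.5) * ss - 0.5])
    big = polygon2mask((h * ss, w * ss), poly).astype(float)
    coverage = big.reshape(h, ss, w, ss).mean(axis=(1, 3))
    img = background_level + (body_level - background_level) * coverage
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    return np.clip(img, 0.0, 1.0)
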