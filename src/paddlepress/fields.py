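"""Core in-memory containers: grid geometry, velocity sequences, scalar fields.

Conventions
-----------
Physical x points rightward, y upward; grids are node-centered with 0-based
indices and units of meters. Arrays are indexed ``[frame, j, i]`` (or
``[j, i]``) with ``j`` the y index (row 0 at the *bottom*, y = y0) and ``i``
the x index. Image import is responsible for flipping the vertical axis so
that "swimming up" is positive y.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidParameterError


@dataclass(frozen=True)
class GridGeometry:
    """Regular node-centered 2D grid: ``x_i = x0 + i*dx``, ``y_j = y0 + j*dy``."""

    nx: int
    ny: int
    dx: float
    dy: float
    x0: float = 0.0
    y0: float = 0.0

    def __post_init__(self) -> None:
        if self.nx < 2 or self.ny < 2:
            raise InvalidParameterError("grid needs at least 2 nodes per axis")
        if self.dx <= 0 or self.dy <= 0:
            raise InvalidParameterError("grid spacing must be positive")

    @property
    def x(self) -> np.ndarray:
        return self.x0 + self.dx * np.arange(self.nx)

    @property
    def y(self) -> np.ndarray:
        return self.y0 + self.dy * np.arange(self.ny)

    def mesh(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, Y) node coordinates, each of shape (ny, nx)."""
        return np.meshgrid(self.x, self.y)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.ny, self.nx)

    def boundary_mask(self) -> np.ndarray:
        b = np.zeros(self.shape, dtype=bool)
        b[0, :] = b[-1, :] = True
        b[:, 0] = b[:, -1] = True
        return b


@dataclass
class VelocityFieldSequence:
    """Time-resolved (u, v) on a regular grid.

    ``u``, ``v`` have shape (n_frames, ny, nx) in m/s; ``valid`` is False
    where the velocimetry produced no vector. ``dt`` is the inter-frame
    interval in seconds.
    """

    u: np.ndarray
    v: np.ndarray
    grid: GridGeometry
    dt: float
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.u.ndim != 3 or self.u.shape != self.v.shape:
            raise InvalidParameterError("u and v must share shape (n_frames, ny, nx)")
        if self.u.shape[1:] != self.grid.shape:
            raise InvalidParameterError("velocity arrays do not match grid shape")
        if self.dt <= 0:
            raise InvalidParameterError("dt must be positive")
        if self.valid is None:
            self.valid = np.ones(self.u.shape, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != self.u.shape:
                raise InvalidParameterError("valid mask does not match velocity shape")
        if not (np.isfinite(self.u[self.valid]).all() and np.isfinite(self.v[self.valid]).all()):
            raise InvalidParameterError("u and v must be finite wherever valid")

    @property
    def n_frames(self) -> int:
        return self.u.shape[0]

    @property
    def times(self) -> np.ndarray:
        return self.dt * np.arange(self.n_frames)

    def speed(self, frame: int) -> np.ndarray:
        return np.hypot(self.u[frame], self.v[frame])


@dataclass
class ScalarField:
    """A scalar quantity on the grid; NaN and ``defined == False`` mark
    nodes where the quantity is not available (e.g. inside a body mask)."""

    values: np.ndarray
    grid: GridGeometry
    units: str = ""
    defined: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise InvalidParameterError("scalar values do not match grid shape")
        if self.defined is None:
            self.defined = np.isfinite(self.values)
        else:
            self.defined = np.asarray(self.defined, dtype=bool)
            if self.defined.shape != self.values.shape:
                raise InvalidParameterError("defined mask does not match values shape")
        if not np.isfinite(self.values[self.defined]).all():
            raise InvalidParameterError("values must be finite wherever defined")


@dataclass(frozen=True)
class FluidProperties:
    """Fluid density (kg/m^3) and dynamic viscosity (Pa s).

    The kinematic viscosity is derived (nu = mu/rho) so the three are
    consistent by construction.
    """

    density: float
    dynamic_viscosity: float

    def __post_init__(self) -> None:
        if self.density <= 0 or self.dynamic_viscosity <= 0:
            raise InvalidParameterError("fluid properties must be positive")

    @property
    def kinematic_viscosity(self) -> float:
        return self.dynamic_viscosity / self.density

    @classmethod
    def from_kinematic(cls, density: float, kinematic_viscosity: float) -> "FluidProperties":
        return cls(density=density, dynamic_viscosity=density * kinematic_viscosity)

    @classmethod
    def seawater(cls) -> "FluidProperties":
        """Seawater near 10-12 degC: rho = 1025 kg/m^3, nu = 1.35e-6 m^2/s."""
        return cls.from_kinematic(1025.0, 1.35e-6)


def bilinear_sample(
    values: np.ndarray,
    defined: np.ndarray,
    grid: GridGeometry,
    points: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Bilinear interpolation of a (ny, nx) array at physical points (n, 2).

    Returns (samples, ok). A sample is ok only when the point lies inside
    the grid and all four stencil nodes are defined; otherwise NaN.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    fx = (pts[:, 0] - grid.x0) / grid.dx
    fy = (pts[:, 1] - grid.y0) / grid.dy
    inside = (fx >= 0) & (fx <= grid.nx - 1) & (fy >= 0) & (fy <= grid.ny - 1)
    i0 = np.clip(np.floor(fx).astype(int), 0, grid.nx - 2)
    j0 = np.clip(np.floor(fy).astype(int), 0, grid.ny - 2)
    tx = fx - i0
    ty = fy - j0
    v00 = values[j0, i0]
    v01 = values[j0, i0 + 1]
    v10 = values[j0 + 1, i0]
    v11 = values[j0 + 1, i0 + 1]
    out = (
        (1 - tx) * (1 - ty) * v00
        + tx * (1 - ty) * v01
        + (1 - tx) * ty * v10
        + tx * ty * v11
    )
    ok = (
        inside
        & defined[j0, i0]
        & defined[j0, i0 + 1]
        & defined[j0 + 1, i0]
        & defined[j0 + 1, i0 + 1]
    )
    out = np.where(ok, out, np.nan)
    return out, ok
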