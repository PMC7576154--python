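"""Reference pressure by a pressure-Poisson solve.

Independent of the eight-path integrator: the gradient field g (from the
same momentum balance) is integrated globally by solving the discrete
least-squares problem ``min_p || G p - g ||`` with G the staggered
forward-difference gradient. Its normal equations are exactly the 5-point
Poisson system lap(p) = div(g) with Neumann conditions dp/dn = g . n, so
this is a standard pressure-Poisson discretization. The constant null
space is fixed by anchoring one node during the solve and re-gauging so
the mean over boundary nodes is zero.
"""
from __future__ import annotations

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import spsolve

from .fields import GridGeometry, ScalarField


def solve_pressure_poisson(
    gx: np.ndarray, gy: np.ndarray, grid: GridGeometry
) -> ScalarField:
    """Pressure (Pa) from a fully defined gradient field (Pa/m)."""
    ny, nx = grid.shape
    n = nx * ny

    def idx(j, i):
        return j * nx + i

    rows, cols, data, rhs = [], [], [], []
    eq = 0
    inv_dx, inv_dy = 1.0 / grid.dx, 1.0 / grid.dy
    # x-edges
    for j in range(ny):
        base = idx(j, 0)
        for i in range(nx - 1):
            rows += [eq, eq]
            cols += [base + i + 1, base + i]
            data += [inv_dx, -inv_dx]
            rhs.append(0.5 * (gx[j, i] + gx[j, i + 1]))
            eq += 1
    # y-edges
    for j in range(ny - 1):
        for i in range(nx):
            rows += [eq, eq]
            cols += [idx(j + 1, i), idx(j, i)]
            data += [inv_dy, -inv_dy]
            rhs.append(0.5 * (gy[j, i] + gy[j + 1, i]))
            eq += 1
    G = sparse.csr_matrix((data, (rows, cols)), shape=(eq, n))
    b = np.asarray(rhs)
    A = (G.T @ G).tocsr()
    bt = G.T @ b
    # anchor node 0 to remove the constant null space (solution is exact
    # because bt is orthogonal to the null space by construction)
    anchor = sparse.csr_matrix(([1.0], ([0], [0])), shape=(n, n))
    p = spsolve((A + anchor).tocsc(), bt).reshape(ny, nx)
    boundary = grid.boundary_mask()
    p = p - p[boundary].mean()
    return ScalarField(values=p, grid=grid, units="Pa")
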