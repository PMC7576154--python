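"""Optional figures: pressure maps with surface force vectors, and force
time series. Figures are outputs only; no computation consumes them."""
from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .fields import ScalarField, VelocityFieldSequence
from .surface_forces import StrokeForceSeries, SurfaceContour


def plot_pressure_map(
    pressure: ScalarField,
    seq: VelocityFieldSequence | None = None,
    frame: int = 0,
    surface: SurfaceContour | None = None,
    surface_pressures: np.ndarray | None = None,
    ax=None,
):
    """Pressure field (Pa) with optional velocity quiver and surface force
    vectors (aquamarine, pointing along -p n)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    g = pressure.grid
    vmax = np.nanmax(np.abs(pressure.values)) or 1.0
    im = ax.imshow(
        pressure.values,
        origin="lower",
        extent=(g.x[0], g.x[-1], g.y[0], g.y[-1]),
        cmap="RdBu_r",
        vmin=-vmax,
        vmax=vmax,
    )
    plt.colorbar(im, ax=ax, label="pressure (Pa)")
    if seq is not None:
        step = max(1, g.nx // 24)
        X, Y = g.mesh()
        sl = (slice(None, None, step), slice(None, None, step))
        ax.quiver(X[sl], Y[sl], seq.u[frame][sl], seq.v[frame][sl], color="0.3", scale_units="xy")
    if surface is not None and surface_pressures is not None:
        f = -surface.normals * surface_pressures[:, None] * surface.ds
        ax.quiver(
            surface.midpoints[:, 0],
            surface.midpoints[:, 1],
            f[:, 0],
            f[:, 1],
            color="aquamarine",
        )
    ax.set_xlabel("x (m)")
    ax.set_ylabel("y (m)")
    return ax


def plot_force_series(series: StrokeForceSeries, ax=None):
    """Pull plotted negative, push positive (display convention only; the
    stored values keep total = pull + push)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    ax.plot(series.times, -np.abs(series.pull), label="pull (-)", color="tab:blue")
    ax.plot(series.times, np.abs(series.push), label="push (+)", color="tab:red")
    ax.plot(series.times, series.total, label="total", color="k")
    ax.axhline(0, color="0.7", lw=0.5)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("force per unit depth (N/m)")
    ax.legend()
    return ax


def save_overview_figures(outdir: Path, seq, pressure_fields, contours) -> None:
    if pressure_fields is None:
        return
    mid = len(pressure_fields) // 2
    ax = plot_pressure_map(pressure_fields[mid], seq, frame=mid)
    ax.figure.savefig(outdir / "pressure_map.png", dpi=150)
    plt.close(ax.figure)
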