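import numpy as np
import pytest

from paddlepress.fields import FluidProperties
from paddlepress.synthetic import make_decaying_vortex_lattice, make_paddle_scene


@pytest.fixture(scope="session")
def fluid():
    return FluidProperties.seawater()


@pytest.fixture(scope="session")
def paddle_scene():
    """Default bending-paddle scene, shared across modules (deterministic)."""
    return make_paddle_scene()


@pytest.fixture(scope="session")
def lattice_128():
    return make_decaying_vortex_lattice(grid_shape=(128, 128))


@pytest.fixture(scope="session")
def lattice_64():
    return make_decaying_vortex_lattice(grid_shape=(64, 64), spacing=2e-4 * 127 / 126)


def two_segment_polyline(angle_deg, frac, L=1.0, n=101, origin=(0.0, 0.0), base_dir_deg=90.0):
    """Exact two-segment centerline: proximal along base_dir, distal rotated
    by angle_deg, break at arc fraction frac."""
    a0 = np.radians(base_dir_deg)
    a1 = a0 + np.radians(angle_deg)
    base = np.asarray(origin, dtype=float)
    e1 = np.array([np.cos(a0), np.sin(a0)])
    e2 = np.array([np.cos(a1), np.sin(a1)])
    bend = base + frac * L * e1
    tip = bend + (1 - frac) * L * e2
    s = np.linspace(0.0, L, n)
    pts = np.where(
        (s[:, None] <= frac * L),
        base + s[:, None] * e1,
        bend + (s[:, None] - frac * L) * e2,
    )
    return pts
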