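import numpy as np
import pytest

from pyresim.core import FieldState, ModelParams
from pyresim.solver import build_geometry


@pytest.fixture
def params():
    """Default parameter set of the condensate model."""
    return ModelParams()


@pytest.fixture
def small_periodic():
    """A 32×32 periodic grid at spacing 0.5 (side 16 ℓ_κ)."""
    return build_geometry({"kind": "periodic_square", "side": 16.0,
                           "spacing": 0.5})


@pytest.fixture
def chloro_small():
    """A quarter-scale chloroplast domain for fast wall-BC tests."""
    return build_geometry({
        "kind": "chloroplast",
        "ellipse_semiaxes": (8.75, 7.29),
        "inner_radius": 4.17,
        "inner_offset": 2.5,
        "spacing": 0.5,
    })


@pytest.fixture
def smooth_state(small_periodic):
    """A smooth low-frequency two-species field on the periodic grid."""
    g = small_periodic
    X, Y = np.meshgrid(g.x, g.y, indexing="xy")
    L = g.side
    phi_s = 0.15 + 0.05 * np.sin(2 * np.pi * X / L) * np.cos(
        2 * np.pi * Y / L)
    phi_ns = 0.08 + 0.03 * np.cos(4 * np.pi * X / L)
    return FieldState(phi_s, phi_ns, 0.0, g.spacing)
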