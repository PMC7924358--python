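import numpy as np
import pytest
from hypothesis import settings

import crevsim as cs

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def reference_geometry():
    """The reference taper junction: 0.02 deg mismatch, 13 mm crevice, 6 mm radius."""
    return cs.CreviceGeometry(alpha_deg=0.02, length=13.0, r_int=6.0)


@pytest.fixture
def flat_profile(reference_geometry):
    """A perfectly smooth cone surface over the full crevice length."""
    g = reference_geometry
    n = int(round(g.length / g.dx))
    x = np.arange(n + 1) * g.dx
    return cs.SurfaceProfile(x, np.zeros_like(x), period=g.length)


@pytest.fixture
def triangle_profile(reference_geometry):
    """The synthetic machined-thread fixture: triangle, 0.27 mm period, 15 um."""
    return cs.generate_fixture_profile(
        "triangle", length=reference_geometry.length, dx=reference_geometry.dx
    )
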