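import math

import pytest
from scipy.integrate import quad

from netrisk.params import SpeciesParameters
from netrisk.scenarios import fig9_holes, fig9_roof_only, fig10_holes


@pytest.fixture(scope="session")
def params():
    return SpeciesParameters()


@pytest.fixture()
def fig9(params):
    """The 14-hole 'typically damaged net' inventory."""
    return fig9_holes(params)


@pytest.fixture()
def fig9_roof(params):
    return fig9_roof_only(params)


@pytest.fixture()
def fig10(params):
    return fig10_holes(params)


def ellipse_perimeter_quadrature(major, minor):
    """Independent arc-length oracle for the ellipse perimeter."""
    a, b = major / 2.0, minor / 2.0
    value, _ = quad(lambda t: math.hypot(a * math.sin(t), b * math.cos(t)),
                    0.0, 2.0 * math.pi, limit=200)
    return value
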