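import numpy as np
import pytest

from saxsfit.core import ScatteringCurve
from saxsfit.validation import sphere_curve, sphere_form_factor


@pytest.fixture(scope="session")
def sphere50():
    """Noise-free analytic sphere curve, R = 50 Å, I0 = 100."""
    return sphere_curve(R=50.0)


@pytest.fixture(scope="session")
def guinier_curve():
    """Ideal Guinier-law curve, Rg = 30 Å, I0 = 50."""
    q = np.linspace(0.002, 0.12, 400)
    I = 50.0 * np.exp(-(q * 30.0) ** 2 / 3.0)
    return ScatteringCurve(q, I, 0.01 * I)
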