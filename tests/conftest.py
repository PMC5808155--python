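import numpy as np
import pytest

from isobole import CurvePair, make_pair


@pytest.fixture
def fig_pair() -> CurvePair:
    """Canonical LACC-satisfying pair: shared y0=1, y_inf=0, s=2; e1=1, e2=2."""
    return make_pair("lacc")


@pytest.fixture
def slopes_pair() -> CurvePair:
    """LACC violated through slopes: s1=1, s2=2 (else y0=1, y_inf=0, e=1)."""
    return make_pair("slopes")


@pytest.fixture
def max_effect_pair() -> CurvePair:
    """LACC violated through asymptotes: y_inf,1=0.3, y_inf,2=0 (s=1, e=1)."""
    return make_pair("max_effect")


@pytest.fixture
def both_pair() -> CurvePair:
    """LACC violated through slopes and asymptotes."""
    return make_pair("both")


@pytest.fixture
def geometric_doses() -> np.ndarray:
    """8-dose conditional grid (zero plus a geometric series) used for fits."""
    return np.concatenate([[0.0], np.geomspace(0.05, 8.0, 7)])
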