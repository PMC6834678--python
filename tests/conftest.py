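import numpy as np
import pytest

from fcrnpk import TraffickingParameters


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def eliminating_params():
    """A single-variant parameter set with net elimination."""
    return TraffickingParameters(
        V_p=2.0, V_e=0.5, Q=1.0, Q_u=0.3,
        f_sort={"x": 0.9}, f_release={"x": 0.8},
    )


@pytest.fixture
def closed_params():
    """f_sort = f_release = 1: no elimination pathway, mass conserved."""
    return TraffickingParameters(
        V_p=2.0, V_e=0.5, Q=1.0, Q_u=0.3,
        f_sort={"x": 1.0}, f_release={"x": 1.0},
    )


def random_params(rng, variant="x", f_max=0.99):
    """Random positive volumes/flows (log-normal) and fractions."""
    vp, ve, q, qu = np.exp(rng.normal(0.0, 1.0, size=4))
    return TraffickingParameters(
        V_p=vp, V_e=ve, Q=q, Q_u=qu,
        f_sort={variant: float(rng.uniform(0.05, f_max))},
        f_release={variant: float(rng.uniform(0.05, f_max))},
    )
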