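import numpy as np
import pytest

from ncis import CircuitParams, peak_conductivity


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def bottle_params():
    """Lab-bottle circuit: C1 = 6.0 pF, ultra-pure-water baseline."""
    return CircuitParams(c1=6.0e-12, kappa_b=5.5e-6)


def well_conditioned_points(rng, n=100, f_lo=1e4, f_hi=3e8):
    """Random (kappa, freq) pairs inside the sensitivity decade band.

    Restricting kappa to within a decade of the peak conductivity keeps
    the complex-difference oracle free of catastrophic cancellation, so
    closed-form and complex routes can be compared at 1e-10 relative.
    """
    freq = 10 ** rng.uniform(np.log10(f_lo), np.log10(f_hi), n)
    kappa = peak_conductivity(freq) * 10 ** rng.uniform(-1.0, 1.0, n)
    return kappa, freq


def round_2sf(x):
    return float(f"{x:.1e}")
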