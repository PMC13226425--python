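import numpy as np
import pytest

from igdyn.decay_fitting import RelaxationRecord
from igdyn.spin_physics import MotionalParameters, back_calculate_rates, make_field


@pytest.fixture(scope="session")
def field():
    """Default field context: 800.13 MHz, rNH 1.02 A, CSA -160 ppm."""
    return make_field()


@pytest.fixture(scope="session")
def record_factory(field):
    """Build RelaxationRecords from motional parameters, with optional noise.

    Noise-free records still carry the error levels (2% rates, 0.02 NOE) so
    chi2 is well defined.
    """

    def make(params: MotionalParameters, tau_c_ns: float = 6.6, seed=None,
             residue_id: int = 1, rate_frac: float = 0.02, noe_sigma: float = 0.02):
        rates = back_calculate_rates(params, tau_c_ns * 1e-9, field)
        r1, r2, noe = rates.R1, rates.R2, rates.NOE
        if seed is not None:
            rng = np.random.default_rng(seed)
            r1 *= 1.0 + rng.normal(0.0, rate_frac)
            r2 *= 1.0 + rng.normal(0.0, rate_frac)
            noe += rng.normal(0.0, noe_sigma)
        return RelaxationRecord(
            residue_id=residue_id,
            R1=r1, R1_err=rate_frac * rates.R1,
            R2=r2, R2_err=rate_frac * rates.R2,
            NOE=noe, NOE_err=noe_sigma,
        )

    return make
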