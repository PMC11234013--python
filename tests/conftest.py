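import dataclasses

import numpy as np
import pytest

import raddkit as rk

#: Reference kinetic values used across tests: cleavage rate of the
#: coupling endonuclease and deamination rates of the catalytic-domain
#: deaminase under excess-enzyme (5 uM) and sub-Km (1 uM) conditions.
K2_CLEAVAGE = 2.97e-3
K1_EXCESS = 5.5e-3
K1_LOW = 9.9e-4

#: Michaelis-Menten reference: Km (uM), Vmax (uM/s) at 100 nM enzyme.
MM_KM = 4.390
MM_VMAX = 5.1397e-4

#: Reference inhibitor potency, nM.
IC50_REF = 226.4


@pytest.fixture(scope="session")
def grid_1h():
    """Standard 1-h, 30-s-interval scan grid (121 points)."""
    return np.arange(0.0, 3601.0, 30.0)


def make_noiseless(base, **overrides):
    return dataclasses.replace(base, noise_sd=0.0, **overrides)


@pytest.fixture(scope="session")
def single_turnover_plate_noiseless():
    design, base = rk.preset("single_turnover")
    return rk.simulate_plate(design, make_noiseless(base), seed=11)


@pytest.fixture
def flat_trace():
    """A constant 10-point trace at 100 RFU."""
    t = np.arange(0.0, 300.0, 30.0)
    return rk.KineticTrace("A1", t, np.full_like(t, 100.0), role="negative_tc")
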