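import math

import numpy as np
import pytest

from samti import (ChargingToy, HarmonicOscillator, LambdaGrid,
                   MetropolisSampler, TorsionChain, WalkerState)


@pytest.fixture
def harmonic():
    return HarmonicOscillator(k0=1.0, k1=4.0)


@pytest.fixture
def charging():
    return ChargingToy(k0=1.0, k1=4.0, c=2.0)


@pytest.fixture
def double_well():
    """Symmetric 10 kT torsional double well (minima at 0 and pi)."""
    return TorsionChain(torsions=[(10.0, 2, math.pi)], k0=0.0, k1=0.0)


@pytest.fixture
def grid101():
    return LambdaGrid(101)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_walker(model, seed=0, lam_index=0):
    return WalkerState(model.initial_coords(), lam_index=lam_index,
                       rng=np.random.default_rng(seed))


def make_sampler(beta=1.0, step_size=1.0, record_interval=1):
    return MetropolisSampler(beta=beta, step_size=step_size,
                             record_interval=record_interval)
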