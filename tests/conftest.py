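import numpy as np
import pytest

from channeliphys import BlockerTruth, GHKCondition, Ion

WILDTYPE_KD0 = 11.4  # uM, equilibrium spermine Kd at 0 mV
WILDTYPE_H = -18.5  # mV
WILDTYPE_K = 36.5  # mV
SPERMINE_UM = 30.0


@pytest.fixture
def voltage_grid():
    """Standard command-voltage grid: -100..+100 mV in 10 mV steps."""
    return np.arange(-100.0, 101.0, 10.0)


@pytest.fixture
def wildtype_truth():
    """Wildtype-like blocker truth: Kd(0)=11.4 uM split 10:1.4 between g and L."""
    return BlockerTruth(gmax=1.0, g=10.0, h=WILDTYPE_H, L=1.4, k=WILDTYPE_K, spm=SPERMINE_UM)


@pytest.fixture
def symmetric_na():
    """150 mM Na on both sides: reversal at exactly 0 mV."""
    return GHKCondition(ions=(Ion("Na", 1, 150.0, 150.0, 1.0),))


def random_ghk_condition(rng) -> GHKCondition:
    """A random bi-ionic condition guaranteed to have permeant ions both sides."""
    ions = [Ion("X", 1, rng.uniform(50, 200), rng.uniform(0, 50), rng.uniform(0.5, 2))]
    if rng.random() < 0.5:
        ions.append(Ion("Y", 1, rng.uniform(0, 50), rng.uniform(50, 200), rng.uniform(0.5, 2)))
    else:
        ions.append(Ion("Ca", 2, 0.0, rng.uniform(1, 10), rng.uniform(0.3, 2)))
    return GHKCondition(ions=tuple(ions))
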