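import numpy as np
import pytest

from pdzscaffold.synthetic_data import (
    DumbbellSpec,
    make_dumbbell,
    mixture_q_grid,
    oligomer_component_curves,
)

OLIGOMER_NAMES = ("1e", "2e", "4e", "8e", "12e", "16e", "20e", "24e")


@pytest.fixture(scope="session")
def q_grid():
    return np.linspace(0.008, 0.40, 120)


@pytest.fixture(scope="session")
def dumbbell():
    return make_dumbbell(DumbbellSpec(), seed=1)


@pytest.fixture(scope="session")
def component_curves():
    """Oligomer component curves on the mixture q grid (built once; the
    Debye sums for the large assemblies dominate the suite's runtime)."""
    return oligomer_component_curves(
        q=mixture_q_grid(), names=OLIGOMER_NAMES, beads_per_domain=30, seed=0
    )
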