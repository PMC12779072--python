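import numpy as np
import pytest

from chemshield.attenuation import CrossSectionTable, ElementXS
from chemshield.formulas import CompoundSpec
from chemshield.io import (
    load_reference_compounds,
    load_reference_docking,
    load_reference_mic,
    load_reference_mmpbsa,
    load_reference_xs,
)
from chemshield.synthetic import SyntheticConfig, gen_gp_table, gen_xs_table


@pytest.fixture(scope="session")
def reference_xs():
    return load_reference_xs()


@pytest.fixture(scope="session")
def reference_compounds():
    return {c.identifier: c for c in load_reference_compounds()}


@pytest.fixture(scope="session")
def docking_fixture():
    return load_reference_docking()


@pytest.fixture(scope="session")
def mmpbsa_fixture():
    return load_reference_mmpbsa()


@pytest.fixture(scope="session")
def mic_fixture():
    return load_reference_mic()


@pytest.fixture(scope="session")
def synthetic_xs():
    """Synthetic cross-section table plus its closed-form laws."""
    return gen_xs_table(SyntheticConfig(seed=11))


@pytest.fixture(scope="session")
def synthetic_gp():
    """Synthetic G-P table plus its closed-form surface."""
    return gen_gp_table(SyntheticConfig(seed=11), kind="EABF")


def power_law_xs(pairs):
    """Cross-section table from pure power laws mu/rho = A * E^(-k).

    ``pairs`` maps symbol -> (Z, A_coeff, k, compton_fraction); the grid
    is sparse because log-log interpolation is exact on power laws.
    """
    grid = np.array([0.01, 0.1, 1.0, 10.0, 100.0])
    elements = {}
    for sym, (z, acoef, k, frac) in pairs.items():
        total = acoef * grid ** (-k)
        elements[sym] = ElementXS(
            symbol=sym, Z=z, energies=grid, total=total, compton=frac * total
        )
    return CrossSectionTable(elements=elements)
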