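import logging

import numpy as np
import pytest

from xtaldose.materials import (
    average_protein_crystal,
    build_crystal_material,
    build_surrounding_material,
)

logging.getLogger("xtaldose").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def water():
    return build_surrounding_material("default_water")


@pytest.fixture(scope="session")
def ice():
    return build_surrounding_material("solutes_mM_in_amorphous_ice")


@pytest.fixture(scope="session")
def protein_crystal():
    return average_protein_crystal()


@pytest.fixture(scope="session")
def water_crystal():
    """Crystal-typed material with a pure-water composition (test seam)."""
    return build_crystal_material(
        explicit_atom_counts={"O": 33.43, "H": 66.86},
        unit_cell_volume_A3=1000.0,
        name="water crystal",
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20260930)
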