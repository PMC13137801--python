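import numpy as np
import pytest

from ferropyro import fields, fixtures, materials, tdgl


@pytest.fixture(scope="session")
def btz():
    return materials.get_material("btz")


@pytest.fixture(scope="session")
def bto():
    return materials.get_material("bto")


@pytest.fixture
def small_grid():
    return fields.SimulationGrid((32, 32), spacing=1e-9)


@pytest.fixture(scope="session")
def relaxed_btz_273():
    """Random multiphase start with defects relaxed at 273 K (shared by the
    domain-structure and classification tests)."""
    shape = (32, 32)
    defect = fixtures.make_defect_field(shape, concentration=0.05, sigma_e=5e5, seed=11)
    config = tdgl.TdglConfig(material="btz", defect_field=defect)
    field = fixtures.make_random_field(shape, amplitude=0.1, seed=11, temperature=273.0)
    return tdgl.evolve(field, config, 2000), config
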