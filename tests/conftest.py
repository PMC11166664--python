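import dataclasses

import pytest

from sacflow.geometry import rectangle_mesh
from sacflow.properties import Loading, effective_bundle, material_table
from sacflow.scenarios import builtin_scenarios, run_scenario


@pytest.fixture(scope="session")
def mats():
    return material_table()


@pytest.fixture(scope="session")
def blood_props(mats):
    return effective_bundle(mats["blood"], mats["gold"], mats["silver"],
                            Loading(0.0, 0.0))


@pytest.fixture(scope="session")
def hnf_props(mats):
    return effective_bundle(mats["blood"], mats["gold"], mats["silver"],
                            Loading(0.01, 0.01))


@pytest.fixture(scope="session")
def channel_mesh():
    return rectangle_mesh(0.7, 0.09, 28, 8)


@pytest.fixture(scope="session")
def rupture_report():
    """Full transient rupture-scenario run at the study defaults (shared by
    the conservation, pressure-anchor and temperature-anchor checks)."""
    return run_scenario(builtin_scenarios()["paper_rupture"])


@pytest.fixture(scope="session")
def uniform_thermal_report():
    """Insulated uniform-temperature run over the full 2.4 s window."""
    return run_scenario(builtin_scenarios()["uniform_thermal"])
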