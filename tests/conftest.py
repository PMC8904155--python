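import pytest

import rgcsim as rs
from rgcsim.cell import (
    CellModel,
    ChannelDensities,
    Morphology,
    Section,
    build_preset_cell,
)
from rgcsim.engine import CompiledCell
from rgcsim.synthetic import make_reduced_pair

#: Train length used throughout the suite: 250 ms = 30 periods at 120 Hz,
#: 50 at 200 Hz -- long enough for stable spike probabilities, short enough
#: for the whole suite to run in minutes.
TRAIN_MS = 250.0


def soma_only_morphology(diameter: float) -> Morphology:
    return Morphology([Section(1, None, "soma", diameter, diameter, 1)])


def soma_only_cell(preset: str, diameter: float, overrides=None) -> CellModel:
    return build_preset_cell(preset, soma_only_morphology(diameter), overrides)


def passive_cell(diameter: float = 20.0) -> CellModel:
    zeros = {c: 0.0 for c in
             ("g_Na", "g_K", "g_KA", "g_KCa", "g_Ca", "g_h", "g_T")}
    return CellModel(soma_only_morphology(diameter),
                     ChannelDensities({"soma": dict(zeros)}))


@pytest.fixture(scope="session")
def electrode() -> rs.ElectrodeModel:
    return rs.ElectrodeModel()


@pytest.fixture(scope="session")
def reduced_pair():
    return make_reduced_pair()


@pytest.fixture(scope="session")
def compiled_pair(reduced_pair, electrode):
    a2, d1 = reduced_pair
    return CompiledCell(a2, electrode), CompiledCell(d1, electrode)


@pytest.fixture(scope="session")
def pw_sweep(compiled_pair):
    """Strength-duration sweep shared by protocol and acceptance tests."""
    a2, d1 = compiled_pair
    return rs.strength_duration_sweep(
        a2, d1, pw_grid=(0.1, 0.3, 0.6, 1.0, 1.2),
        duration=TRAIN_MS, resolution=5.0)


@pytest.fixture(scope="session")
def ipg_sweep_result(compiled_pair):
    """IPG sweep at PW 0.5 ms, 1 uA resolution (to resolve the small
    threshold reduction the gap produces)."""
    a2, d1 = compiled_pair
    return rs.ipg_sweep(a2, d1, ipg_grid=(0.0, 0.2, 1.0), pulse_width=0.5,
                        duration=TRAIN_MS, resolution=1.0)
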