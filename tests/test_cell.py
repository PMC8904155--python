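import io
import math

import pytest

import rgcsim as rs
from rgcsim.cell import (
    AXON_KINDS,
    Morphology,
    Section,
    attach_axon,
    build_preset_cell,
    preset_densities,
)
from .conftest import soma_only_morphology

# every base (non-derived) conductance printed in the two preset tables,
# (preset, region, channel, S/cm^2)
PRINTED_BASE_VALUES = [
    ("A2", "soma", "g_Na", 0.35), ("A2", "soma", "g_K", 0.12),
    ("A2", "soma", "g_Ca", 0.137), ("A2", "soma", "g_h", 0.0),
    ("A2", "soma", "g_T", 0.004),
    ("A2", "dendrite", "g_Na", 0.1), ("A2", "dendrite", "g_K", 0.05),
    ("A2", "dendrite", "g_Ca", 0.05), ("A2", "dendrite", "g_h", 0.0),
    ("A2", "dendrite", "g_T", 0.0),
    ("D1", "soma", "g_Na", 0.2), ("D1", "soma", "g_K", 0.211),
    ("D1", "soma", "g_Ca", 0.013), ("D1", "soma", "g_h", 0.0001),
    ("D1", "soma", "g_T", 0.0024),
    ("D1", "dendrite", "g_Na", 0.08), ("D1", "dendrite", "g_K", 0.08),
    ("D1", "dendrite", "g_Ca", 0.01), ("D1", "dendrite", "g_h", 3e-5),
    ("D1", "dendrite", "g_T", 0.001),
    # shared axon bands
    ("A2", "AH", "g_Na", 0.8), ("A2", "AH", "g_K", 0.6),
    ("A2", "SOCB", "g_Na", 2.4), ("A2", "SOCB", "g_K", 0.8),
    ("A2", "NS", "g_Na", 0.9), ("A2", "NS", "g_K", 0.6),
    ("D1", "DA", "g_Na", 0.8), ("D1", "DA", "g_K", 0.6),
]


@pytest.mark.parametrize("preset,region,channel,value", PRINTED_BASE_VALUES)
def test_preset_reproduces_printed_conductance(preset, region, channel, value):
    """Every base conductance of the preset tables is reproduced exactly."""
    assert preset_densities(preset).get(region, channel) == value


@pytest.mark.parametrize("preset", ["A2", "D1"])
def test_derived_conductance_ratios(preset):
    """A-type and Ca-activated K scale with the delayed rectifier:
    g_KA = 3 g_K and g_KCa = 0.004 g_K, exactly, in every region."""
    dens = preset_densities(preset)
    for region, chans in dens.regions.items():
        assert chans["g_KA"] == 3.0 * chans["g_K"]
        assert chans["g_KCa"] == 0.004 * chans["g_K"]


def test_unknown_preset_rejected():
    with pytest.raises(ValueError):
        build_preset_cell("B3", soma_only_morphology(20.0))


def test_soma_diameter_override_leaves_densities_unchanged():
    cell = build_preset_cell("D1", soma_only_morphology(12.0),
                             {"soma_diameter": 20.0})
    soma = cell.morphology.root
    assert soma.diameter == 20.0 and soma.length == 20.0
    assert cell.densities.get("soma", "g_Ca") == 0.013
    assert cell.densities.get("soma", "g_h") == 0.0001


def test_override_of_missing_region_or_channel_rejected():
    m = soma_only_morphology(20.0)
    with pytest.raises(KeyError):
        build_preset_cell("A2", m, {"densities": {"axon_zz": {"g_Na": 1.0}}})
    with pytest.raises((KeyError, ValueError)):
        build_preset_cell("A2", m, {"densities": {"soma": {"g_Zn": 1.0}}})
    with pytest.raises(KeyError):
        build_preset_cell("A2", m, {"soma_diametre": 20.0})


class TestMorphologyInvariants:
    def test_single_root_required(self):
        with pytest.raises(ValueError):
            Morphology([Section(1, None, "soma", 20, 20), Section(2, None, "soma", 20, 20)])

    def test_distal_axon_is_terminal(self):
        secs = [Section(1, None, "soma", 20, 20),
                Section(2, 1, "DA", 100, 1),
                Section(3, 2, "dendrite", 10, 1)]
        with pytest.raises(ValueError):
            Morphology(secs)

    def test_axon_band_order_enforced(self):
        secs = [Section(1, None, "soma", 20, 20),
                Section(2, 1, "SOCB", 40, 1),
                Section(3, 2, "AH", 40, 1)]
        with pytest.raises(ValueError):
            Morphology(secs)

    def test_nonpositive_geometry_rejected(self):
        with pytest.raises(ValueError):
            Section(1, None, "soma", 0.0, 20)
        with pytest.raises(ValueError):
            Section(1, None, "soma", 20, -1.0)


class TestAttachAxon:
    def test_appends_four_bands_in_order(self):
        m = attach_axon(soma_only_morphology(20.0))
        kinds = [s.kind for s in m.axon_sections()]
        assert kinds == list(AXON_KINDS)
        # chained: AH on soma, then each on its predecessor
        by_id = {s.id: s for s in m.sections}
        for sec in m.axon_sections():
            parent = by_id[sec.parent_id]
            assert parent.kind == ("soma" if sec.kind == "AH" else
                                   AXON_KINDS[AXON_KINDS.index(sec.kind) - 1])

    def test_zero_length_band_rejected(self):
        with pytest.raises(ValueError):
            attach_axon(soma_only_morphology(20.0), {"DA": (0.0, 1.0)})

    def test_total_axon_path_length_is_band_sum(self):
        bands = {"AH": (40.0, 1.0), "SOCB": (40.0, 1.0),
                 "NS": (90.0, 0.6), "DA": (310.0, 1.0)}
        m = attach_axon(soma_only_morphology(20.0), bands)
        total = sum(s.length for s in m.axon_sections())
        assert math.isclose(total, sum(v[0] for v in bands.values()),
                            abs_tol=1e-9)

    def test_double_attach_rejected(self):
        m = attach_axon(soma_only_morphology(20.0))
        with pytest.raises(ValueError):
            attach_axon(m)


class TestSWC:
    MINIMAL = "1 1 0 0 0 10 -1\n2 3 10 0 0 1 1\n3 3 30 0 0 1 2\n"

    def test_minimal_file_yields_soma_and_dendrite(self):
        m = rs.load_swc(self.MINIMAL)
        kinds = sorted(s.kind for s in m.sections)
        assert kinds == ["dendrite", "soma"]
        dend = next(s for s in m.sections if s.kind == "dendrite")
        assert dend.length == pytest.approx(20.0)
        assert dend.diameter == pytest.approx(2.0)

    def test_negative_radius_rejected(self):
        bad = self.MINIMAL.replace("2 3 10 0 0 1 1", "2 3 10 0 0 -1 1")
        with pytest.raises(ValueError):
            rs.load_swc(bad)

    def test_orphan_parent_rejected(self):
        bad = self.MINIMAL + "4 3 40 0 0 1 99\n"
        with pytest.raises(ValueError):
            rs.load_swc(bad)

    def test_multiple_roots_rejected(self):
        bad = self.MINIMAL + "4 1 100 0 0 10 -1\n"
        with pytest.raises(ValueError):
            rs.load_swc(bad)

    def test_point_count_matches_line_count(self):
        m = rs.load_swc(self.MINIMAL)
        assert m.point_count() == 3

    @pytest.mark.parametrize("seed", [0, 7])
    def test_write_then_load_is_fixed_point(self, seed):
        """Serializing a loaded morphology and re-parsing reproduces the
        identical section tree (kinds, geometry, paths) and byte-identical
        SWC text."""
        from rgcsim.synthetic import StylizedCellSpec, generate_stylized_morphology
        gen = generate_stylized_morphology(
            StylizedCellSpec(12.0, 144.0, "bi", seed=seed))
        buf1 = io.StringIO()
        rs.write_swc(gen, buf1)
        m1 = rs.load_swc(buf1.getvalue())
        assert m1.point_count() == len(buf1.getvalue().strip().splitlines())
        buf2 = io.StringIO()
        rs.write_swc(m1, buf2)
        m2 = rs.load_swc(buf2.getvalue())
        key = lambda m: [(s.kind, s.length, s.diameter, s.n_segments,
                          [tuple(map(float, p)) for p in s.path])
                         for s in m.sections]
        assert key(m1) == key(m2)
        buf3 = io.StringIO()
        rs.write_swc(m2, buf3)
        assert buf2.getvalue() == buf3.getvalue()
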