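"""Morphology and biophysical parameterization of retinal ganglion cell models.

A :class:`Morphology` is a tree of :class:`Section` objects rooted at the soma.
Axons are represented by the four canonical RGC bands — axon hillock (AH),
sodium channel band (SOCB, the high-Na axon initial segment), narrow segment
(NS) and distal axon (DA) — appended in that order.  Channel-density presets
for the A2-monostratified and D1-bistratified cells are shipped as a
structured-text data file (``data/conductances.yaml``) so they are auditable
without reading code; the A-type and Ca-activated K conductances are derived
from the delayed-rectifier density as ``g_KA = 3 g_K`` and
``g_KCa = 0.004 g_K``.
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping, Optional

import yaml

logger = logging.getLogger(__name__)

SECTION_KINDS = ("soma", "dendrite", "AH", "SOCB", "NS", "DA")
AXON_KINDS = ("AH", "SOCB", "NS", "DA")
CHANNELS = ("g_Na", "g_K", "g_KA", "g_KCa", "g_Ca", "g_h", "g_T")
BASE_CHANNELS = ("g_Na", "g_K", "g_Ca", "g_h", "g_T")

#: Axon band geometry used when none is supplied: {kind: (length um, diameter um)}.
#: These are configurable stand-ins for the published RGC axon parameterization;
#: nothing downstream assumes these exact numbers.
DEFAULT_AXON_BANDS = {
    "AH": (40.0, 1.0),
    "SOCB": (40.0, 1.0),
    "NS": (90.0, 0.6),
    "DA": (1000.0, 1.0),
}

#: Maximum segment length (um) per section kind used to pick n_segments.  Finer
#: resolution near the soma and along the thin axon bands resolves the
#: extracellular potential gradient under a 200 um disk electrode.
MAX_SEG_LENGTH = {
    "soma": 10.0,
    "AH": 10.0,
    "SOCB": 10.0,
    "NS": 10.0,
    "dendrite": 25.0,
    "DA": 25.0,
}


def segments_for(kind: str, length: float) -> int:
    return max(1, int(math.ceil(length / MAX_SEG_LENGTH[kind])))


@dataclass
class Section:
    """One unbranched cable piece of a morphology tree."""

    id: int
    parent_id: Optional[int]
    kind: str
    length: float  # um
    diameter: float  # um
    n_segments: int = 1
    path: Optional[list[tuple[float, float, float]]] = None

    def __post_init__(self) -> None:
        if self.kind not in SECTION_KINDS:
            raise ValueError(f"unknown section kind {self.kind!r}")
        if not self.length > 0:
            raise ValueError(f"section {self.id}: length must be > 0")
        if not self.diameter > 0:
            raise ValueError(f"section {self.id}: diameter must be > 0")
        if self.n_segments < 1:
            raise ValueError(f"section {self.id}: n_segments must be >= 1")


@dataclass
class Morphology:
    """Connected acyclic tree of sections rooted at the soma."""

    sections: list[Section]
    soma_position: tuple[float, float, float] = (0.0, 0.0, 0.0)
    stratification: str = "monostratified"

    def __post_init__(self) -> None:
        self.validate()

    # -- structure ---------------------------------------------------------
    def by_id(self, sid: int) -> Section:
        return self._index[sid]

    @property
    def root(self) -> Section:
        return self._root

    def children(self, sid: int) -> list[Section]:
        return [s for s in self.sections if s.parent_id == sid]

    def axon_sections(self) -> list[Section]:
        return [s for s in self.sections if s.kind in AXON_KINDS]

    def validate(self) -> None:
        ids = [s.id for s in self.sections]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate section ids")
        self._index = {s.id: s for s in self.sections}
        roots = [s for s in self.sections if s.parent_id is None]
        if len(roots) != 1:
            raise ValueError(f"morphology must have exactly one root, got {len(roots)}")
        self._root = roots[0]
        if self._root.kind != "soma":
            raise ValueError("root section must be the soma")
        # connectivity + acyclicity: walk to root from every node
        for s in self.sections:
            seen = set()
            cur = s
            while cur.parent_id is not None:
                if cur.id in seen:
                    raise ValueError("cycle detected in morphology")
                seen.add(cur.id)
                if cur.parent_id not in self._index:
                    raise ValueError(f"section {cur.id} references missing parent {cur.parent_id}")
                cur = self._index[cur.parent_id]
        # DA is terminal
        for s in self.sections:
            if s.kind == "DA" and self.children(s.id):
                raise ValueError("DA (distal axon) must be terminal")
        # axon band order: bands present must form a subsequence of
        # soma -> AH -> SOCB -> NS -> DA (never attached to a dendrite,
        # never out of order)
        order = {k: i for i, k in enumerate(("soma",) + AXON_KINDS)}
        for s in self.axon_sections():
            parent = self._index[s.parent_id]
            if parent.kind not in order or order[parent.kind] >= order[s.kind]:
                raise ValueError(
                    f"axon band {s.kind} cannot attach to {parent.kind}"
                )

    def next_id(self) -> int:
        return max(s.id for s in self.sections) + 1

    def point_count(self) -> int:
        """Total number of 3-D sample points over all section paths."""
        return sum(len(s.path) for s in self.sections if s.path is not None)


@dataclass
class ChannelDensities:
    """Per-region maximum conductances, S/cm^2, for the seven channels."""

    regions: dict[str, dict[str, float]]

    def __post_init__(self) -> None:
        for region, chans in self.regions.items():
            if region not in SECTION_KINDS:
                raise ValueError(f"unknown region {region!r}")
            for name, val in chans.items():
                if name not in CHANNELS:
                    raise ValueError(f"unknown channel {name!r}")
                if val < 0:
                    raise ValueError(f"{region}.{name} must be >= 0")

    def get(self, region: str, channel: str) -> float:
        return self.regions[region][channel]

    def copy(self) -> "ChannelDensities":
        return ChannelDensities({r: dict(c) for r, c in self.regions.items()})


@dataclass
class PassiveParams:
    """Passive cable properties (standard mammalian-RGC modeling values)."""

    membrane_capacitance: float = 1.0  # uF/cm^2
    axial_resistivity: float = 110.0  # Ohm*cm
    leak_conductance: float = 5e-5  # S/cm^2
    leak_reversal: float = -65.0  # mV
    temperature: float = 22.0  # degC

    def __post_init__(self) -> None:
        for name in ("membrane_capacitance", "axial_resistivity", "leak_conductance"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class CellModel:
    """Morphology + densities + passive parameters + reversal potentials."""

    morphology: Morphology
    densities: ChannelDensities
    passive: PassiveParams = field(default_factory=PassiveParams)
    reversal_potentials: dict[str, float] = field(
        default_factory=lambda: {"Na": 35.0, "K": -75.0, "h": -32.0}
    )
    label: str = ""

    def __post_init__(self) -> None:
        for s in self.morphology.sections:
            if s.kind not in self.densities.regions:
                raise ValueError(f"no channel densities for region {s.kind!r}")

    def with_soma_diameter(self, diameter: float) -> "CellModel":
        """Return a copy with the soma section rescaled to the given diameter.

        The soma is modeled as a cylinder of equal length and diameter, so both
        are rescaled; densities are untouched.
        """
        sections = []
        for s in self.morphology.sections:
            if s.kind == "soma":
                sections.append(replace(s, length=diameter, diameter=diameter))
            else:
                sections.append(replace(s))
        morph = Morphology(sections, self.morphology.soma_position, self.morphology.stratification)
        return CellModel(morph, self.densities.copy(), replace(self.passive),
                         dict(self.reversal_potentials), self.label)

    def with_density(self, region: str, channel: str, value: float) -> "CellModel":
        """Return a copy with one maximum conductance replaced."""
        dens = self.densities.copy()
        if region not in dens.regions or channel not in dens.regions[region]:
            raise KeyError(f"no density entry {region}.{channel}")
        dens.regions[region][channel] = value
        return CellModel(self.morphology, dens, replace(self.passive),
                         dict(self.reversal_potentials), self.label)


# ---------------------------------------------------------------------------
# presets


def _load_conductance_tables() -> dict:
    with resources.files("rgcsim.data").joinpath("conductances.yaml").open() as fh:
        return yaml.safe_load(fh)


def _derive(chans: Mapping[str, float]) -> dict[str, float]:
    out = dict(chans)
    out["g_KA"] = 3.0 * out["g_K"]
    out["g_KCa"] = 0.004 * out["g_K"]
    return out


def preset_densities(name: str) -> ChannelDensities:
    """Channel densities of the named preset ('A2' or 'D1'), axon included."""
    tables = _load_conductance_tables()
    if name not in ("A2", "D1"):
        raise ValueError(f"unknown preset {name!r} (expected 'A2' or 'D1')")
    regions = {r: _derive(c) for r, c in tables[name].items()}
    regions.update({r: _derive(c) for r, c in tables["axon"].items()})
    return ChannelDensities(regions)


def build_preset_cell(
    name: str,
    morphology: Morphology,
    overrides: Optional[Mapping] = None,
) -> CellModel:
    """Build an A2 or D1 cell model on the given morphology.

    ``overrides`` may contain ``soma_diameter`` (um) and/or
    ``densities: {region: {channel: value}}`` entries; overriding a
    non-existent region or channel is an error.
    """
    densities = preset_densities(name)
    cell = CellModel(morphology, densities, label=name)
    if overrides:
        unknown = set(overrides) - {"soma_diameter", "densities"}
        if unknown:
            raise KeyError(f"unknown override keys: {sorted(unknown)}")
        if "soma_diameter" in overrides:
            cell = cell.with_soma_diameter(float(overrides["soma_diameter"]))
        for region, chans in (overrides.get("densities") or {}).items():
            for channel, value in chans.items():
                cell = cell.with_density(region, channel, float(value))
        cell.label = name
    return cell


# ---------------------------------------------------------------------------
# axon attachment


def attach_axon(
    morphology: Morphology,
    band_geometry: Optional[Mapping[str, tuple[float, float]]] = None,
) -> Morphology:
    """Append the four axon bands (AH, SOCB, NS, DA) rooted at the soma."""
    if morphology.axon_sections():
        raise ValueError("morphology already has axon bands")
    bands = dict(DEFAULT_AXON_BANDS)
    if band_geometry:
        bands.update({k: tuple(v) for k, v in band_geometry.items()})
    for kind in AXON_KINDS:
        length, diam = bands[kind]
        if length <= 0 or diam <= 0:
            raise ValueError(f"axon band {kind}: length and diameter must be > 0")
    sections = [replace(s) for s in morphology.sections]
    sid = morphology.next_id()
    parent = morphology.root.id
    for kind in AXON_KINDS:
        length, diam = bands[kind]
        sections.append(
            Section(sid, parent, kind, length, diam, segments_for(kind, length))
        )
        parent = sid
        sid += 1
    return Morphology(sections, morphology.soma_position, morphology.stratification)


# ---------------------------------------------------------------------------
# SWC I/O

_SWC_KIND = {1: "soma", 2: "DA", 3: "dendrite", 4: "dendrite"}
_KIND_SWC = {"soma": 1, "dendrite": 3, "AH": 2, "SOCB": 2, "NS": 2, "DA": 2}


def load_swc(stream) -> Morphology:
    """Parse a standard 7-column SWC file into a morphology.

    Contiguous runs of same-type points become one section; the soma is the
    SWC type-1 point(s).  SWC axon points (type 2) are mapped to the distal
    axon; unknown type codes map to dendrite with a logged warning.  Radii are
    um.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    points: dict[int, tuple[int, float, float, float, float, Optional[int]]] = {}
    order: list[int] = []
    for lineno, raw in enumerate(stream, 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        cols = line.split()
        if len(cols) != 7:
            raise ValueError(f"SWC line {lineno}: expected 7 columns")
        pid = int(cols[0])
        ptype = int(cols[1])
        x, y, z, radius = (float(c) for c in cols[2:6])
        parent = int(cols[6])
        if radius <= 0:
            raise ValueError(f"SWC line {lineno}: non-positive radius")
        if ptype not in _SWC_KIND:
            logger.warning("SWC line %d: unknown type code %d mapped to dendrite", lineno, ptype)
        points[pid] = (ptype, x, y, z, radius, None if parent == -1 else parent)
        order.append(pid)
    if not points:
        raise ValueError("empty SWC file")
    roots = [pid for pid in order if points[pid][5] is None]
    if len(roots) != 1:
        raise ValueError(f"SWC must have exactly one root, got {len(roots)}")
    for pid in order:
        parent = points[pid][5]
        if parent is not None and parent not in points:
            raise ValueError(f"SWC point {pid} references missing parent {parent}")

    children: dict[int, list[int]] = {pid: [] for pid in order}
    for pid in order:
        parent = points[pid][5]
        if parent is not None:
            children[parent].append(pid)

    def kind_of(pid: int) -> str:
        return _SWC_KIND.get(points[pid][0], "dendrite")

    sections: list[Section] = []
    sec_id = [1]

    def emit_section(point_ids: list[int], parent_section: Optional[int]) -> int:
        pts = [points[p] for p in point_ids]
        path = [(p[1], p[2], p[3]) for p in pts]
        length = 0.0
        for a, b in zip(path, path[1:]):
            length += math.dist(a, b)
        kind = kind_of(point_ids[-1])
        if length == 0.0:  # single-point section (e.g. one-point soma)
            length = 2.0 * pts[-1][4]
        diameter = 2.0 * sum(p[4] for p in pts) / len(pts)
        sid = sec_id[0]
        sec_id[0] += 1
        sections.append(Section(sid, parent_section, kind, length, diameter,
                                segments_for(kind, length), path))
        return sid

    root = roots[0]
    # soma: contiguous type-1 run from the root
    soma_pts = [root]
    cur = root
    while True:
        soma_children = [c for c in children[cur] if kind_of(c) == "soma"]
        if len(soma_children) == 1 and len(children[cur]) >= 1:
            cur = soma_children[0]
            soma_pts.append(cur)
        else:
            break
    soma_sid = emit_section(soma_pts, None)

    # walk the rest: unbranched same-kind runs become sections; a section's
    # path is exactly its own SWC points (the hop from the parent's last
    # point is not part of the child's geometry in this dialect)
    def walk(start: int, parent_section: int) -> None:
        run = [start]
        cur = start
        while True:
            kids = children[cur]
            if len(kids) == 1 and kind_of(kids[0]) == kind_of(cur):
                cur = kids[0]
                run.append(cur)
            else:
                break
        sid = emit_section(run, parent_section)
        for k in children[cur]:
            walk(k, sid)

    for c in children[soma_pts[-1]]:
        if kind_of(c) != "soma":
            walk(c, soma_sid)
    for p in soma_pts[:-1]:
        for c in children[p]:
            if kind_of(c) != "soma":
                walk(c, soma_sid)

    soma_xyz = points[root][1:4]
    return Morphology(sections, tuple(soma_xyz))


def write_swc(morphology: Morphology, stream) -> None:
    """Serialize a morphology with path points back to SWC text."""
    pid = [1]
    lines: list[str] = []

    def write_point(ptype: int, xyz, radius: float, parent: int) -> int:
        this = pid[0]
        pid[0] += 1
        lines.append(f"{this} {ptype} {float(xyz[0])!r} {float(xyz[1])!r} {float(xyz[2])!r} {float(radius)!r} {parent}")
        return this

    def write_section(sec: Section, parent_point: int, parent_xyz) -> None:
        if sec.path is None:
            raise ValueError(f"section {sec.id} has no path points; cannot serialize")
        ptype = _KIND_SWC[sec.kind]
        last = parent_point
        pts = list(sec.path)
        # a child whose path begins exactly at the parent's tail shares that
        # point rather than duplicating it
        if parent_xyz is not None and pts and tuple(pts[0]) == tuple(parent_xyz):
            pts = pts[1:]
        for xyz in pts:
            last = write_point(ptype, xyz, sec.diameter / 2.0, last)
        tail_xyz = sec.path[-1] if sec.path else parent_xyz
        for child in morphology.children(sec.id):
            write_section(child, last, tail_xyz)

    write_section(morphology.root, -1, None)
    stream.write("\n".join(lines) + "\n")
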