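"""Synthetic morphologies and traces standing in for the study's inputs.

The stylized generator emulates the gross geometry of the two modeled cells —
A2-monostratified: 20 um soma, 320 um dendritic field; D1-bistratified:
12 um soma, 144 um field in two stratification planes — with an invented
radial branching pattern (real reconstructions were used in the original
study and are not bundled).  The reduced pair carries the exact preset
channel densities on a soma + four-band axon and is the workhorse for the
stimulation protocols: the two models differ only in soma diameter and
soma-region densities, so comparisons between them are controlled.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np

from .cell import (
    DEFAULT_AXON_BANDS,
    CellModel,
    Morphology,
    Section,
    attach_axon,
    build_preset_cell,
    segments_for,
)

#: Gross geometry of the two modeled cells: (soma diameter um, field diameter um)
A2_GEOMETRY = (20.0, 320.0)
D1_GEOMETRY = (12.0, 144.0)


@dataclass
class StylizedCellSpec:
    soma_diameter: float  # um
    dendritic_field_diameter: float  # um
    stratification: str = "mono"  # or "bi"
    branches_per_layer: int = 6
    depth_of_layers: tuple[float, ...] = (10.0, 30.0)  # um below the soma
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dendritic_field_diameter <= self.soma_diameter:
            raise ValueError("dendritic field must exceed the soma diameter")
        if self.branches_per_layer < 1:
            raise ValueError("branches_per_layer must be >= 1")
        if self.stratification not in ("mono", "bi"):
            raise ValueError("stratification must be 'mono' or 'bi'")


def generate_stylized_morphology(spec: StylizedCellSpec) -> Morphology:
    """Soma cylinder + radial dendrites in one or two stratification planes.

    Each primary dendrite runs straight from the soma edge to the dendritic
    field radius in its plane, as two tapering sections (1.5 um proximal,
    0.5 um distal by default).  Azimuths are jittered deterministically from
    the seed.
    """
    rng = np.random.default_rng(spec.seed)
    soma_d = spec.soma_diameter
    sections = [Section(1, None, "soma", soma_d, soma_d, 1,
                        path=[(0.0, 0.0, 0.0), (soma_d, 0.0, 0.0)])]
    planes = (spec.depth_of_layers[0],) if spec.stratification == "mono" \
        else spec.depth_of_layers[:2]
    field_r = spec.dendritic_field_diameter / 2.0
    sid = 2
    for plane_z in planes:
        base = rng.uniform(0.0, 2.0 * np.pi)
        for b in range(spec.branches_per_layer):
            az = base + 2.0 * np.pi * b / spec.branches_per_layer \
                + rng.normal(0.0, 0.05)
            ux, uy = np.cos(az), np.sin(az)
            # radial extent measured from the soma center; dendrite starts at
            # the soma surface and descends to its stratification plane
            r0, r1 = soma_d / 2.0, field_r
            rmid = (r0 + r1) / 2.0
            p_start = (r0 * ux, r0 * uy, 0.0)
            p_mid = (rmid * ux, rmid * uy, plane_z)
            p_end = (r1 * ux, r1 * uy, plane_z)
            l_prox = float(np.linalg.norm(np.subtract(p_mid, p_start)))
            l_dist = float(np.linalg.norm(np.subtract(p_end, p_mid)))
            sections.append(Section(sid, 1, "dendrite", l_prox, 1.5,
                                    segments_for("dendrite", l_prox),
                                    path=[p_start, p_mid]))
            sections.append(Section(sid + 1, sid, "dendrite", l_dist, 0.5,
                                    segments_for("dendrite", l_dist),
                                    path=[p_mid, p_end]))
            sid += 2
    strat = "monostratified" if spec.stratification == "mono" else "bistratified"
    return Morphology(sections, (0.0, 0.0, 0.0), strat)


def morphology_hash(morph: Morphology) -> str:
    """Stable digest of section structure + geometry (for determinism checks)."""
    h = hashlib.sha256()
    for s in sorted(morph.sections, key=lambda s: s.id):
        h.update(f"{s.id},{s.parent_id},{s.kind},{s.length:.9f},{s.diameter:.9f},{s.n_segments}".encode())
        if s.path is not None:
            for p in s.path:
                h.update(np.asarray(p, dtype=float).tobytes())
    return h.hexdigest()


def make_reduced_pair(budget: int = 30):
    """Reduced A2-like / D1-like model pair for protocol-scale simulations.

    Each model is a soma cylinder carrying its preset's soma densities plus
    (when the compartment budget allows) the four axon bands with the shared
    axon densities; the distal axon is truncated to fit the budget.  The two
    models differ only in soma diameter and preset densities and are placed
    identically relative to the electrode.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")

    def build(name: str, soma_d: float) -> CellModel:
        soma = Section(1, None, "soma", soma_d, soma_d, 1)
        morph = Morphology([soma])
        fixed = sum(segments_for(k, DEFAULT_AXON_BANDS[k][0]) for k in ("AH", "SOCB", "NS"))
        if budget >= 2 + fixed:
            da_segs = min(budget - 1 - fixed,
                          segments_for("DA", DEFAULT_AXON_BANDS["DA"][0]))
            bands = dict(DEFAULT_AXON_BANDS)
            bands["DA"] = (da_segs * 25.0, bands["DA"][1])
            morph = attach_axon(morph, bands)
        return build_preset_cell(name, morph)

    return build("A2", A2_GEOMETRY[0]), build("D1", D1_GEOMETRY[0])


DEFAULT_SPIKE_TEMPLATE_MS = 1.0  # base width of the synthetic spike


def make_synthetic_trace(
    spike_times,
    duration: float = 100.0,
    dt: float = 0.05,
    noise_amplitude: float = 0.0,
    seed: int = 0,
    baseline: float = -65.0,
    peak: float = 40.0,
    template_width: float = DEFAULT_SPIKE_TEMPLATE_MS,
):
    """Deterministic synthetic voltage trace with planted triangular spikes.

    Returns ``(time, trace, ground_truth_times)``.  Spikes closer together
    than the template width are rejected (they would overlap).
    """
    spike_times = np.sort(np.asarray(spike_times, dtype=float))
    if np.any(spike_times < 0) or np.any(spike_times > duration):
        raise ValueError("spike times must lie within the duration")
    if len(spike_times) > 1 and np.min(np.diff(spike_times)) < template_width:
        raise ValueError("overlapping spike templates")
    time = np.arange(0.0, duration + dt / 2.0, dt)
    trace = np.full_like(time, baseline)
    half = template_width / 2.0
    for ts in spike_times:
        # triangular spike peaking at ts + half
        mask = (time >= ts) & (time <= ts + template_width)
        frac = 1.0 - np.abs(time[mask] - (ts + half)) / half
        trace[mask] = baseline + (peak - baseline) * np.clip(frac, 0.0, 1.0)
    if noise_amplitude > 0:
        rng = np.random.default_rng(seed)
        trace = trace + rng.normal(0.0, noise_amplitude, size=len(time))
    return time, trace, spike_times
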