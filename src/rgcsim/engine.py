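"""Compartmental cable integration with extracellular drive.

The cable equation ``C_m dV/dt = -I_ion + axial coupling`` is integrated with
an implicit theta scheme (backward Euler by default, Crank-Nicolson optional)
on the morphology tree.  The extracellular potential enters through the
standard extracellular mechanism: axial currents are driven by the
intracellular potential ``V_i = V_m + V_e``, where ``V_e`` at each compartment
is the disk-electrode unit-current potential scaled by the instantaneous
stimulus current (quasi-static coupling).  The linear system at each step is
solved exactly with the Hines elimination for trees (children are numbered
after their parents, eliminated leaf-to-root).

Gating variables advance by an implicit first-order update, which keeps them
in [0, 1] for any bounded voltage trajectory; the submembrane Ca pool uses
the same implicit update.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from numba import njit

from . import membrane as mb
from .cell import CellModel, Section
from .stim import ElectrodeModel, PulseTrain, map_extracellular


class SimulationDiverged(RuntimeError):
    def __init__(self, t_ms: float):
        super().__init__(f"membrane voltage diverged (|V| > 1000 mV) at t = {t_ms:.3f} ms")
        self.t_ms = t_ms


@dataclass
class SolverSettings:
    dt: float = 0.01  # ms
    method: str = "backward_euler"  # or "crank_nicolson"
    spike_threshold: float = -20.0  # mV
    spike_deadtime: float = 1.5  # ms
    v_init: float = -65.0  # mV
    settle_ms: float = 300.0  # zero-stimulus settling before t = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.spike_deadtime < 0:
            raise ValueError("spike_deadtime must be >= 0")
        if self.method not in ("backward_euler", "crank_nicolson"):
            raise ValueError(f"unknown method {self.method!r}")

    @property
    def theta(self) -> float:
        return 1.0 if self.method == "backward_euler" else 0.5


@dataclass
class SimResult:
    time: np.ndarray  # ms
    soma_voltage: np.ndarray  # mV
    spike_times: np.ndarray  # ms
    stimulus_trace: np.ndarray  # uA at each step
    metadata: dict = field(default_factory=dict)
    section_voltages: Optional[np.ndarray] = None  # (n_steps+1, n_comp)


# ---------------------------------------------------------------------------
# geometry -> per-compartment arrays


def _section_compartments(sec: Section, start: np.ndarray, direction: np.ndarray):
    """Centers (n,3) and end point of a section laid out from ``start``."""
    n = sec.n_segments
    if sec.path is not None and len(sec.path) >= 2:
        pts = np.asarray(sec.path, dtype=float)
        seglen = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        arc = np.concatenate([[0.0], np.cumsum(seglen)])
        total = arc[-1]
        centers_s = (np.arange(n) + 0.5) / n * total
        centers = np.empty((n, 3))
        for k, s in enumerate(centers_s):
            j = min(np.searchsorted(arc, s) - 1, len(seglen) - 1)
            j = max(j, 0)
            frac = (s - arc[j]) / seglen[j] if seglen[j] > 0 else 0.0
            centers[k] = pts[j] + frac * (pts[j + 1] - pts[j])
        return centers, pts[-1].copy()
    # straight layout along `direction`
    centers = start[None, :] + direction[None, :] * ((np.arange(n) + 0.5) / n * sec.length)[:, None]
    end = start + direction * sec.length
    return centers, end


class CompiledCell:
    """Cell model flattened to per-compartment arrays for the solver.

    Compartments are ordered so every parent precedes its children (Hines
    ordering).  Compartment 0 is the soma.
    """

    def __init__(self, cell: CellModel, electrode: Optional[ElectrodeModel] = None):
        self.cell = cell
        self.electrode = electrode
        morph = cell.morphology
        chan_order = ("g_Na", "g_K", "g_KA", "g_KCa", "g_Ca", "g_h", "g_T")

        comp_parent: list[int] = []
        comp_xyz: list[np.ndarray] = []
        comp_len: list[float] = []
        comp_diam: list[float] = []
        comp_kind: list[str] = []

        soma_pos = np.asarray(morph.soma_position, dtype=float)

        def add_section(sec: Section, parent_comp: int, start: np.ndarray,
                        direction: np.ndarray) -> None:
            centers, end = _section_compartments(sec, start, direction)
            seg_l = sec.length / sec.n_segments
            first = len(comp_parent)
            for k in range(sec.n_segments):
                comp_parent.append(parent_comp if k == 0 else first + k - 1)
                comp_xyz.append(centers[k])
                comp_len.append(seg_l)
                comp_diam.append(sec.diameter)
                comp_kind.append(sec.kind)
            last = len(comp_parent) - 1
            for child in morph.children(sec.id):
                add_section(child, last, end, direction)

        root = morph.root
        # soma modeled as a cylinder of equal length and diameter, centered at
        # soma_position; children start from the soma center
        add_section(root, -1, soma_pos, np.array([1.0, 0.0, 0.0]))

        self.parent = np.asarray(comp_parent, dtype=np.int64)
        self.kind = comp_kind
        xyz = np.vstack(comp_xyz)
        # place the cell in the electrode frame: soma center on-axis at the
        # standoff depth (disk in the z = 0 plane)
        if electrode is not None:
            offset = np.array([electrode.center[0], electrode.center[1],
                               electrode.center[2] + electrode.distance_to_soma])
            xyz = xyz - xyz[0] + offset
        self.xyz = xyz

        length_cm = np.asarray(comp_len) * 1e-4
        diam_cm = np.asarray(comp_diam) * 1e-4
        area_cm2 = np.pi * diam_cm * length_cm
        self.area_cm2 = area_cm2

        passive = cell.passive
        self.c_nF = passive.membrane_capacitance * area_cm2 * 1e3
        self.g_leak_uS = passive.leak_conductance * area_cm2 * 1e6
        self.E_leak = passive.leak_reversal

        gmax = np.zeros((len(comp_parent), len(chan_order)))
        for i, kind in enumerate(comp_kind):
            dens = cell.densities.regions[kind]
            for j, ch in enumerate(chan_order):
                gmax[i, j] = dens.get(ch, 0.0) * area_cm2[i] * 1e6  # uS
        self.gmax_uS = gmax

        # axial conductance (uS) between each compartment and its parent:
        # series half-segment resistances
        Ra = passive.axial_resistivity  # Ohm*cm
        half_R = Ra * (length_cm / 2.0) / (np.pi * (diam_cm / 2.0) ** 2)  # Ohm
        g_par = np.zeros(len(comp_parent))
        for i, p in enumerate(comp_parent):
            if p >= 0:
                g_par[i] = 1.0 / (half_R[i] + half_R[p]) * 1e6  # uS
        self.g_parent_uS = g_par

        if electrode is not None:
            self.ve_scale = map_extracellular(self.xyz, electrode)  # mV/uA
        else:
            self.ve_scale = np.zeros(len(comp_parent))

        params = mb.MembraneParams(
            E_leak=passive.leak_reversal,
            temperature=passive.temperature,
            **{f"E_{k}": v for k, v in cell.reversal_potentials.items() if k in ("Na", "K", "h")},
        )
        self.params = params
        self._rest_cache: dict = {}

    @property
    def n_comp(self) -> int:
        return len(self.parent)

    def initial_state(self, v: float):
        n = self.n_comp
        v0 = np.full(n, v)
        gates = np.empty((n, len(mb.GATES)))
        for gi, g in enumerate(mb.GATES):
            gates[:, gi] = mb.steady_state(g, v)
        ca = np.full(n, self.params.Ca_rest)
        return v0, gates, ca

    def resting_state(self, settings: SolverSettings):
        """State after settling with zero stimulus (cached per dt/method)."""
        key = (settings.dt, settings.method, settings.v_init, settings.settle_ms)
        if key not in self._rest_cache:
            v0, gates, ca = self.initial_state(settings.v_init)
            n_steps = int(round(settings.settle_ms / settings.dt))
            stim = np.zeros(n_steps)
            out = _run_kernel(
                self.parent, self.c_nF, self.area_cm2, self.g_parent_uS, self.gmax_uS,
                self.g_leak_uS, self.E_leak, self.params.E_Na, self.params.E_K,
                self.params.E_h, self.ve_scale, stim, np.zeros(n_steps), -1,
                settings.dt, 1.0, v0, gates, ca, mb.RATE_TABLE,
                self.params.Ca_o, self.params.Ca_rest, self.params.ca_tau,
                mb.ca_influx_coefficient(self.params.pool_depth),
                self.params.kca_half, self.params.temperature, False,
            )
            vtrace, _, vf, gf, caf, div_idx = out
            if div_idx >= 0:
                raise SimulationDiverged(div_idx * settings.dt)
            self._rest_cache[key] = (vf, gf, caf)
        vf, gf, caf = self._rest_cache[key]
        return vf.copy(), gf.copy(), caf.copy()

    # -- main entry --------------------------------------------------------
    def run(
        self,
        train: Optional[PulseTrain] = None,
        settings: Optional[SolverSettings] = None,
        duration: Optional[float] = None,
        i_inject_nA: Optional[np.ndarray] = None,
        inject_comp: int = 0,
        record_sections: bool = False,
        from_rest: bool = True,
    ) -> SimResult:
        settings = settings or SolverSettings()
        if duration is None:
            if train is None:
                raise ValueError("need a train or an explicit duration")
            duration = train.duration
        n_steps = int(round(duration / settings.dt))
        tmid = (np.arange(n_steps) + 0.5) * settings.dt
        stim = np.asarray(train.current(tmid), dtype=float) if train is not None else np.zeros(n_steps)
        inj = np.zeros(n_steps) if i_inject_nA is None else np.asarray(i_inject_nA, dtype=float)
        if len(inj) != n_steps:
            raise ValueError("i_inject_nA must have one sample per time step")

        if from_rest:
            v0, gates, ca = self.resting_state(settings)
        else:
            v0, gates, ca = self.initial_state(settings.v_init)

        vtrace, vall, vf, gf, caf, div_idx = _run_kernel(
            self.parent, self.c_nF, self.area_cm2, self.g_parent_uS, self.gmax_uS,
            self.g_leak_uS, self.E_leak, self.params.E_Na, self.params.E_K,
            self.params.E_h, self.ve_scale, stim, inj,
            inject_comp if i_inject_nA is not None else -1,
            settings.dt, settings.theta, v0, gates, ca, mb.RATE_TABLE,
            self.params.Ca_o, self.params.Ca_rest, self.params.ca_tau,
            mb.ca_influx_coefficient(self.params.pool_depth),
            self.params.kca_half, self.params.temperature, record_sections,
        )
        if div_idx >= 0:
            raise SimulationDiverged(div_idx * settings.dt)
        time = np.arange(n_steps + 1) * settings.dt
        spikes = detect_spikes(vtrace, time, settings)
        meta = {
            "dt": settings.dt,
            "method": settings.method,
            "n_comp": self.n_comp,
            "duration_ms": duration,
            "label": self.cell.label,
        }
        if train is not None:
            meta["train"] = {
                "amplitude_uA": train.amplitude, "pw_ms": train.pulse_width,
                "ipg_ms": train.ipg, "freq_hz": train.frequency,
            }
        meta["config_hash"] = hashlib.sha256(
            json.dumps(meta, sort_keys=True).encode()).hexdigest()[:16]
        return SimResult(
            time=time, soma_voltage=vtrace, spike_times=spikes,
            stimulus_trace=stim, metadata=meta,
            section_voltages=vall if record_sections else None,
        )


def simulate(
    cell: CellModel,
    train: Optional[PulseTrain] = None,
    electrode: Optional[ElectrodeModel] = None,
    settings: Optional[SolverSettings] = None,
    **kwargs,
) -> SimResult:
    """One-shot convenience wrapper: compile the cell and run the train."""
    return CompiledCell(cell, electrode).run(train, settings, **kwargs)


# ---------------------------------------------------------------------------
# numba kernel


@njit(cache=True)
def _run_kernel(parent, c_nF, area_cm2, g_par, gmax, g_leak, E_leak, E_Na, E_K, E_h,
                ve_scale, stim, inj, inj_comp, dt, theta, v0, gates0, ca0,
                rate_table, ca_o, ca_rest, ca_tau, ca_coef, kca_half,
                temperature, record_all):
    n = v0.shape[0]
    n_steps = stim.shape[0]
    n_gates = gates0.shape[1]

    v = v0.copy()
    gates = gates0.copy()
    ca = ca0.copy()

    vtrace = np.empty(n_steps + 1)
    vtrace[0] = v[0]
    if record_all:
        vall = np.empty((n_steps + 1, n))
        vall[0] = v
    else:
        vall = np.empty((1, n))

    diag = np.empty(n)
    rhs = np.empty(n)
    ve_old = np.zeros(n)
    G_ion = np.empty(n)
    S_ion = np.empty(n)

    nernst_fac = 1e3 * 8.31446 * (temperature + 273.15) / (2.0 * 96485.332)
    div_idx = -1

    for step in range(n_steps):
        I_now = stim[step]
        # gating update (implicit, from V at step start)
        for i in range(n):
            Vi = v[i]
            for gi in range(n_gates):
                fa = int(rate_table[gi, 0, 0])
                a = _rate_nb(fa, rate_table[gi, 0, 1], rate_table[gi, 0, 2],
                             rate_table[gi, 0, 3], Vi)
                fb = int(rate_table[gi, 1, 0])
                b = _rate_nb(fb, rate_table[gi, 1, 1], rate_table[gi, 1, 2],
                             rate_table[gi, 1, 3], Vi)
                x = gates[i, gi]
                gates[i, gi] = (x + dt * a) / (1.0 + dt * (a + b))
            # Ca pool update from Ca-carrying currents at step start
            e_ca = nernst_fac * math.log(ca_o / ca[i])
            g_ca_uS = gmax[i, 4] * gates[i, 5] ** 3
            g_t_uS = gmax[i, 6] * gates[i, 7] ** 2 * gates[i, 8]
            i_ca_nA = (g_ca_uS + g_t_uS) * (Vi - e_ca)
            i_ca_density = i_ca_nA * 1e-3 / area_cm2[i]  # uA/cm^2
            # only inward Ca flux loads the pool (GHK-like rectification);
            # extrusion is the first-order removal term
            influx = -i_ca_density * ca_coef
            if influx < 0.0:
                influx = 0.0
            new_ca = (ca[i] + dt * (influx + ca_rest / ca_tau)) / (1.0 + dt / ca_tau)
            ca[i] = max(new_ca, 1e-12)

        # membrane conductances and source terms (uS, nA)
        for i in range(n):
            e_ca = nernst_fac * math.log(ca_o / ca[i])
            gNa = gmax[i, 0] * gates[i, 0] ** 3 * gates[i, 1]
            gK = gmax[i, 1] * gates[i, 2] ** 4
            gKA = gmax[i, 2] * gates[i, 3] ** 3 * gates[i, 4]
            x = (ca[i] / kca_half) ** 2
            gKCa = gmax[i, 3] * (x / (1.0 + x))
            gCa = gmax[i, 4] * gates[i, 5] ** 3
            gH = gmax[i, 5] * gates[i, 6]
            gT = gmax[i, 6] * gates[i, 7] ** 2 * gates[i, 8]
            G_ion[i] = gNa + gK + gKA + gKCa + gCa + gH + gT + g_leak[i]
            S_ion[i] = (gNa * E_Na + (gK + gKA + gKCa) * E_K
                        + (gCa + gT) * e_ca + gH * E_h + g_leak[i] * E_leak)

        # assemble theta-scheme system
        for i in range(n):
            ve_new_i = ve_scale[i] * I_now
            diag[i] = c_nF[i] / dt + theta * G_ion[i]
            rhs[i] = c_nF[i] / dt * v[i] + theta * S_ion[i]
            if theta < 1.0:
                rhs[i] += (1.0 - theta) * (S_ion[i] - G_ion[i] * v[i])
            if inj_comp == i and inj.shape[0] > 0:
                rhs[i] += inj[step]
        for i in range(n):
            p = parent[i]
            if p >= 0:
                g = g_par[i]
                ve_i = ve_scale[i] * I_now
                ve_p = ve_scale[p] * I_now
                diag[i] += theta * g
                diag[p] += theta * g
                # extracellular drive (implicit side)
                rhs[i] += theta * g * (ve_p - ve_i)
                rhs[p] += theta * g * (ve_i - ve_p)
                if theta < 1.0:
                    # explicit axial + drive at step start
                    ve_i_o = ve_old[i]
                    ve_p_o = ve_old[p]
                    ax = g * ((v[p] + ve_p_o) - (v[i] + ve_i_o))
                    rhs[i] += (1.0 - theta) * ax
                    rhs[p] -= (1.0 - theta) * ax

        # Hines elimination: children have larger indices than parents
        for i in range(n - 1, 0, -1):
            p = parent[i]
            g = theta * g_par[i]
            f = g / diag[i]
            diag[p] -= f * g
            rhs[p] += f * rhs[i]
        v[0] = rhs[0] / diag[0]
        for i in range(1, n):
            p = parent[i]
            v[i] = (rhs[i] + theta * g_par[i] * v[p]) / diag[i]

        for i in range(n):
            ve_old[i] = ve_scale[i] * I_now

        vtrace[step + 1] = v[0]
        if record_all:
            vall[step + 1] = v
        if abs(v[0]) > 1000.0:
            div_idx = step + 1
            break
        if step % 200 == 0:
            ok = True
            for i in range(n):
                if abs(v[i]) > 1000.0 or not math.isfinite(v[i]):
                    ok = False
            if not ok:
                div_idx = step + 1
                break

    return vtrace, vall, v, gates, ca, div_idx


@njit(cache=True)
def _rate_nb(form, A, V0, B, V):
    if form == 0:
        x = (V - V0) / B
        if abs(x) < 1e-7:
            return A * B * (1.0 + x / 2.0)
        return A * (V - V0) / (1.0 - math.exp(-x))
    elif form == 1:
        return A * math.exp((V - V0) / B)
    else:
        return A / (1.0 + math.exp(-(V - V0) / B))


# ---------------------------------------------------------------------------
# spike extraction


def detect_spikes(trace, time, settings: Optional[SolverSettings] = None) -> np.ndarray:
    """Upward threshold-crossing times, ignoring re-crossings within the
    dead time."""
    s = settings or SolverSettings()
    trace = np.asarray(trace, dtype=float)
    time = np.asarray(time, dtype=float)
    if not np.all(np.isfinite(trace)):
        raise ValueError("trace must be finite")
    thr = s.spike_threshold
    up = np.flatnonzero((trace[:-1] < thr) & (trace[1:] >= thr)) + 1
    out: list[float] = []
    last = -np.inf
    for idx in up:
        t = time[idx]
        if t - last >= s.spike_deadtime:
            out.append(t)
            last = t
    return np.asarray(out)


def spike_metrics(
    trace,
    time,
    settings: Optional[SolverSettings] = None,
    pulse_onsets=None,
    resting: Optional[float] = None,
) -> dict:
    """Width at half max, peak and latency of the first spike in the trace.

    Width is measured at half of (peak - resting) on the first spike; latency
    is the first threshold crossing minus the most recent preceding cathodic
    phase onset (0 if no onsets are given).
    """
    s = settings or SolverSettings()
    trace = np.asarray(trace, dtype=float)
    time = np.asarray(time, dtype=float)
    spikes = detect_spikes(trace, time, s)
    if len(spikes) == 0:
        raise ValueError("no spike in trace")
    t_cross = spikes[0]
    idx = int(np.searchsorted(time, t_cross))
    if resting is None:
        resting = trace[0]
    # peak: maximum until the trace falls back below threshold
    j = idx
    while j < len(trace) - 1 and trace[j] >= s.spike_threshold:
        j += 1
    peak_idx = idx + int(np.argmax(trace[idx:j + 1]))
    peak = float(trace[peak_idx])
    half = resting + (peak - resting) / 2.0
    # walk outward from the peak to the half-level crossings
    left = peak_idx
    while left > 0 and trace[left - 1] >= half:
        left -= 1
    right = peak_idx
    while right < len(trace) - 1 and trace[right + 1] >= half:
        right += 1

    def _interp(i0, i1):
        if trace[i1] == trace[i0]:
            return time[i0]
        f = (half - trace[i0]) / (trace[i1] - trace[i0])
        return time[i0] + f * (time[i1] - time[i0])

    t_left = _interp(left - 1, left) if left > 0 else time[left]
    t_right = _interp(right + 1, right) if right < len(trace) - 1 else time[right]
    width = float(t_right - t_left)

    latency = 0.0
    if pulse_onsets is not None and len(pulse_onsets) > 0:
        onsets = np.asarray(pulse_onsets, dtype=float)
        before = onsets[onsets <= t_cross]
        if len(before):
            latency = float(t_cross - before[-1])
    return {"width_at_half_max": width, "peak": peak,
            "latency_from_pulse_onset": latency}
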