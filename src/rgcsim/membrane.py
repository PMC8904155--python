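"""Channel gating kinetics, ionic currents and the intracellular Ca pool.

The membrane carries seven conductances: fast Na, delayed-rectifier K, A-type
K, Ca-activated K, L-type Ca, HCN (h) and low-threshold T-type Ca, plus leak.
Voltage-gated rates are loaded from ``data/kinetics.yaml`` (one alpha/beta
record per gate, each a linoid / exponential / sigmoid form), so every kinetic
constant is auditable in one place.  The Ca-activated K conductance has no
voltage gate; its open fraction follows intracellular Ca through
``(Ca/Kd)^2 / (1 + (Ca/Kd)^2)``.  The Ca reversal potential is computed by
Nernst from the intracellular pool, which is a single well-mixed submembrane
shell with first-order removal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Mapping

import numpy as np
import yaml
from numba import njit

GATES = ("m", "h", "n", "a", "hA", "c", "q", "tm", "th")
_FORM_IDS = {"linoid": 0, "exp": 1, "sigmoid": 2}

FARADAY = 96485.332  # C/mol
GAS_CONSTANT = 8.31446  # J/(mol*K)


def _load_kinetics() -> dict:
    with resources.files("rgcsim.data").joinpath("kinetics.yaml").open() as fh:
        return yaml.safe_load(fh)


_KINETICS = _load_kinetics()

#: (n_gates, 2, 4) array of [form_id, A, V0, B] for (alpha, beta) of each gate,
#: in GATES order.  Shared with the simulation engine.
RATE_TABLE = np.zeros((len(GATES), 2, 4))
for _gi, _g in enumerate(GATES):
    for _ri, _r in enumerate(("alpha", "beta")):
        rec = _KINETICS[_g][_r]
        RATE_TABLE[_gi, _ri] = (_FORM_IDS[rec["form"]], rec["A"], rec["V0"], rec["B"])


@njit(cache=True)
def _rate(form: int, A: float, V0: float, B: float, V: float) -> float:
    if form == 0:  # linoid, removable singularity at V0
        x = (V - V0) / B
        if abs(x) < 1e-7:
            return A * B * (1.0 + x / 2.0)
        return A * (V - V0) / (1.0 - math.exp(-x))
    elif form == 1:  # exponential
        return A * math.exp((V - V0) / B)
    else:  # sigmoid
        return A / (1.0 + math.exp(-(V - V0) / B))


def rate_functions(gate: str, V: float) -> tuple[float, float]:
    """Opening and closing rates (1/ms) of the named gate at voltage V (mV).

    Finite everywhere, including at the removable singularities of the
    linoid rate form.
    """
    if gate not in GATES:
        raise KeyError(f"unknown gate {gate!r}; known gates: {GATES}")
    if not math.isfinite(V):
        raise ValueError("V must be finite")
    gi = GATES.index(gate)
    a = _rate(int(RATE_TABLE[gi, 0, 0]), RATE_TABLE[gi, 0, 1], RATE_TABLE[gi, 0, 2],
              RATE_TABLE[gi, 0, 3], V)
    b = _rate(int(RATE_TABLE[gi, 1, 0]), RATE_TABLE[gi, 1, 1], RATE_TABLE[gi, 1, 2],
              RATE_TABLE[gi, 1, 3], V)
    return a, b


def steady_state(gate: str, V: float) -> float:
    a, b = rate_functions(gate, V)
    return a / (a + b)


def time_constant(gate: str, V: float) -> float:
    a, b = rate_functions(gate, V)
    return 1.0 / (a + b)


@dataclass
class MembraneParams:
    """Reversal potentials and Ca-pool parameters."""

    E_Na: float = 35.0  # mV
    E_K: float = -75.0  # mV
    E_h: float = -32.0  # mV
    E_leak: float = -65.0  # mV
    Ca_o: float = 1.8  # mM extracellular Ca
    Ca_rest: float = 1e-4  # mM resting intracellular Ca
    pool_depth: float = 0.1  # um, submembrane shell depth
    ca_tau: float = 1.5  # ms, first-order Ca removal
    kca_half: float = 1e-3  # mM, K_Ca half-activation
    temperature: float = 22.0  # degC

    def __post_init__(self) -> None:
        for name in ("Ca_o", "Ca_rest", "pool_depth", "ca_tau", "kca_half"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class GatingState:
    """Gate open fractions and intracellular Ca of one compartment."""

    m: float
    h: float
    n: float
    a: float
    hA: float
    c: float
    q: float
    tm: float
    th: float
    Ca_i: float = 1e-4  # mM

    def __post_init__(self) -> None:
        for g in GATES:
            v = getattr(self, g)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"gate {g} = {v} outside [0, 1]")
        if self.Ca_i <= 0:
            raise ValueError("Ca_i must be > 0")

    @classmethod
    def at_voltage(cls, V: float, Ca_i: float = 1e-4) -> "GatingState":
        """State with every gate at its steady state for voltage V."""
        return cls(*(steady_state(g, V) for g in GATES), Ca_i=Ca_i)


def nernst_ca(Ca_i: float, Ca_o: float, temperature: float = 22.0) -> float:
    """Ca reversal potential (mV) by Nernst (divalent)."""
    T = temperature + 273.15
    return 1e3 * GAS_CONSTANT * T / (2.0 * FARADAY) * math.log(Ca_o / Ca_i)


def kca_open_fraction(Ca_i: float, kca_half: float) -> float:
    x = (Ca_i / kca_half) ** 2
    return x / (1.0 + x)


def ionic_current(
    V: float,
    state: GatingState,
    densities: Mapping[str, float],
    params: MembraneParams | None = None,
    leak_conductance: float = 5e-5,
) -> tuple[float, dict[str, float]]:
    """Total membrane current density (uA/cm^2, outward positive) + breakdown.

    ``densities`` maps channel names (``g_Na`` ... ``g_T``) to maximum
    conductances in S/cm^2; missing channels are treated as absent.  The leak
    is always included.
    """
    p = params or MembraneParams()
    g = {k: densities.get(k, 0.0) for k in
         ("g_Na", "g_K", "g_KA", "g_KCa", "g_Ca", "g_h", "g_T")}
    E_Ca = nernst_ca(state.Ca_i, p.Ca_o, p.temperature)
    # conductance * 1000 converts (S/cm^2 * mV) to uA/cm^2
    per = {
        "Na": 1e3 * g["g_Na"] * state.m ** 3 * state.h * (V - p.E_Na),
        "K": 1e3 * g["g_K"] * state.n ** 4 * (V - p.E_K),
        "KA": 1e3 * g["g_KA"] * state.a ** 3 * state.hA * (V - p.E_K),
        "KCa": 1e3 * g["g_KCa"] * kca_open_fraction(state.Ca_i, p.kca_half) * (V - p.E_K),
        "Ca": 1e3 * g["g_Ca"] * state.c ** 3 * (V - E_Ca),
        "T": 1e3 * g["g_T"] * state.tm ** 2 * state.th * (V - E_Ca),
        "h": 1e3 * g["g_h"] * state.q * (V - p.E_h),
        "leak": 1e3 * leak_conductance * (V - p.E_leak),
    }
    return sum(per.values()), per


def step_calcium(
    I_Ca: float, Ca_i: float, dt: float, params: MembraneParams | None = None
) -> float:
    """Advance the submembrane Ca pool one step (implicit Euler).

    ``I_Ca`` is the total Ca-carrying current density (uA/cm^2, outward
    positive; inward Ca current is negative and raises Ca_i).
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    p = params or MembraneParams()
    # only inward Ca flux (negative current) loads the pool; outward flux
    # through Ca channels is negligible in reality (GHK rectification) and
    # extrusion is represented by the first-order removal term
    influx = max(-I_Ca, 0.0) * ca_influx_coefficient(p.pool_depth)  # mM/ms
    new = (Ca_i + dt * (influx + p.Ca_rest / p.ca_tau)) / (1.0 + dt / p.ca_tau)
    return max(new, 1e-12)


def ca_influx_coefficient(pool_depth_um: float) -> float:
    """mM/ms of pool Ca per uA/cm^2 of inward Ca current."""
    depth_cm = pool_depth_um * 1e-4
    # (1e-6 A/cm^2) / (2 F depth) -> mol/(cm^3 s) -> mM/ms
    return 1e-6 / (2.0 * FARADAY * depth_cm) * 1e6 * 1e-3
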