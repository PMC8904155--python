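"""Run configuration: schema validation, defaults and normalization.

A run config is a YAML/dict document with four blocks (``cell``,
``electrode``, ``solver``, ``protocol``) plus ``output_dir`` and ``seed``.
Unknown keys anywhere are rejected (typo guard); units are fixed by the
schema (ms, uA, um, Hz, S/cm^2).  Normalization fills defaults and is
idempotent.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from typing import Any, Mapping

import yaml

_CELL_KEYS = {"preset", "swc_path", "soma_diameter", "densities",
              "reduced_budget", "stylized"}
_STYLIZED_KEYS = {"soma_diameter", "dendritic_field_diameter", "stratification",
                  "branches_per_layer", "seed"}
_ELECTRODE_KEYS = {"radius_um", "conductivity_S_per_m", "distance_to_soma_um"}
_SOLVER_KEYS = {"dt_ms", "method", "spike_threshold_mV", "spike_deadtime_ms"}
_PROTOCOL_KEYS = {"amplitude_uA", "pw_ms", "ipg_ms", "freq_hz", "duration_ms",
                  "tune_freq_hz", "test_freq_hz", "resolution_uA",
                  "amp_min_uA", "amp_max_uA", "amp_step_uA",
                  "pw_grid_ms", "ipg_grid_ms", "level", "target_rate_hz",
                  "region", "channel", "target_value", "step_nA"}
_TOP_KEYS = {"cell", "electrode", "solver", "protocol", "output_dir", "seed"}


class ConfigError(ValueError):
    """Schema violation, with the offending field path in the message."""


@dataclass
class RunConfig:
    cell: dict = field(default_factory=lambda: {"preset": "A2"})
    electrode: dict = field(default_factory=dict)
    solver: dict = field(default_factory=dict)
    protocol: dict = field(default_factory=dict)
    output_dir: str = "results"
    seed: int = 0

    def hash(self) -> str:
        digest = hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()
        return digest[:16]


def _check_keys(block: Mapping, allowed: set, path: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ConfigError(f"{path}: unknown key(s) {sorted(unknown)}")


def validate_config(source) -> RunConfig:
    """Parse + validate a config (YAML text, stream, dict or RunConfig).

    Fills defaults, checks units/signs, rejects unknown keys.  Idempotent:
    ``validate_config(validate_config(c)) == validate_config(c)``.
    """
    if isinstance(source, RunConfig):
        raw: dict = asdict(source)
    elif isinstance(source, Mapping):
        raw = {k: (dict(v) if isinstance(v, Mapping) else v) for k, v in source.items()}
    else:
        text = source if isinstance(source, str) else source.read()
        raw = yaml.safe_load(text) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    _check_keys(raw, _TOP_KEYS, "config")

    cell = dict(raw.get("cell") or {"preset": "A2"})
    _check_keys(cell, _CELL_KEYS, "cell")
    preset = cell.setdefault("preset", "A2")
    if preset not in ("A2", "D1"):
        raise ConfigError("cell.preset: must be 'A2' or 'D1'")
    if "stylized" in cell and cell["stylized"] is not None:
        _check_keys(cell["stylized"], _STYLIZED_KEYS, "cell.stylized")
    if "soma_diameter" in cell and cell["soma_diameter"] is not None:
        if float(cell["soma_diameter"]) <= 0:
            raise ConfigError("cell.soma_diameter: must be > 0 um")
    cell.setdefault("reduced_budget", 30)

    electrode = dict(raw.get("electrode") or {})
    _check_keys(electrode, _ELECTRODE_KEYS, "electrode")
    electrode.setdefault("radius_um", 100.0)
    electrode.setdefault("conductivity_S_per_m", 0.1)
    electrode.setdefault("distance_to_soma_um", 50.0)
    for k in _ELECTRODE_KEYS:
        if float(electrode[k]) <= 0:
            raise ConfigError(f"electrode.{k}: must be > 0")

    solver = dict(raw.get("solver") or {})
    _check_keys(solver, _SOLVER_KEYS, "solver")
    solver.setdefault("dt_ms", 0.01)
    solver.setdefault("method", "backward_euler")
    solver.setdefault("spike_threshold_mV", -20.0)
    solver.setdefault("spike_deadtime_ms", 1.5)
    if float(solver["dt_ms"]) <= 0:
        raise ConfigError("solver.dt_ms: must be > 0")
    if solver["method"] not in ("backward_euler", "crank_nicolson"):
        raise ConfigError("solver.method: unknown method")

    protocol = dict(raw.get("protocol") or {})
    _check_keys(protocol, _PROTOCOL_KEYS, "protocol")
    if "amplitude_uA" in protocol and protocol["amplitude_uA"] is not None:
        if float(protocol["amplitude_uA"]) < 0:
            raise ConfigError(
                "protocol.amplitude_uA: amplitude is a magnitude (>= 0); "
                "polarity is fixed cathodic-first")
    for k in ("pw_ms", "freq_hz", "duration_ms"):
        if k in protocol and protocol[k] is not None and float(protocol[k]) <= 0:
            raise ConfigError(f"protocol.{k}: must be > 0")
    if "ipg_ms" in protocol and protocol["ipg_ms"] is not None:
        if float(protocol["ipg_ms"]) < 0:
            raise ConfigError("protocol.ipg_ms: must be >= 0")

    return RunConfig(
        cell=cell, electrode=electrode, solver=solver, protocol=protocol,
        output_dir=str(raw.get("output_dir", "results")),
        seed=int(raw.get("seed", 0)),
    )


def build_from_config(cfg: RunConfig):
    """Instantiate (CellModel, ElectrodeModel, SolverSettings) from a config."""
    from .cell import build_preset_cell, load_swc
    from .engine import SolverSettings
    from .stim import ElectrodeModel
    from .synthetic import StylizedCellSpec, generate_stylized_morphology, make_reduced_pair

    cell_cfg = cfg.cell
    overrides: dict[str, Any] = {}
    if cell_cfg.get("soma_diameter"):
        overrides["soma_diameter"] = float(cell_cfg["soma_diameter"])
    if cell_cfg.get("densities"):
        overrides["densities"] = cell_cfg["densities"]

    if cell_cfg.get("swc_path"):
        with open(cell_cfg["swc_path"]) as fh:
            morph = load_swc(fh)
        cell = build_preset_cell(cell_cfg["preset"], morph, overrides or None)
    elif cell_cfg.get("stylized"):
        sp = dict(cell_cfg["stylized"])
        spec = StylizedCellSpec(
            soma_diameter=float(sp.get("soma_diameter", 20.0)),
            dendritic_field_diameter=float(sp.get("dendritic_field_diameter", 320.0)),
            stratification=sp.get("stratification", "mono"),
            branches_per_layer=int(sp.get("branches_per_layer", 6)),
            seed=int(sp.get("seed", cfg.seed)),
        )
        morph = generate_stylized_morphology(spec)
        cell = build_preset_cell(cell_cfg["preset"], morph, overrides or None)
    else:
        a2, d1 = make_reduced_pair(int(cell_cfg.get("reduced_budget", 30)))
        cell = a2 if cell_cfg["preset"] == "A2" else d1
        if "soma_diameter" in overrides:
            cell = cell.with_soma_diameter(overrides["soma_diameter"])
        for region, chans in (overrides.get("densities") or {}).items():
            for ch, val in chans.items():
                cell = cell.with_density(region, ch, float(val))

    el = ElectrodeModel(
        radius=float(cfg.electrode["radius_um"]),
        medium_conductivity=float(cfg.electrode["conductivity_S_per_m"]),
        distance_to_soma=float(cfg.electrode["distance_to_soma_um"]),
    )
    settings = SolverSettings(
        dt=float(cfg.solver["dt_ms"]),
        method=cfg.solver["method"],
        spike_threshold=float(cfg.solver["spike_threshold_mV"]),
        spike_deadtime=float(cfg.solver["spike_deadtime_ms"]),
    )
    return cell, el, settings
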