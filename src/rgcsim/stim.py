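"""Biphasic pulse trains and the extracellular field of a disk electrode.

Stimuli are symmetric charge-balanced biphasic pulse trains, cathodic phase
first, with an optional zero-current interphase gap (IPG) between the two
phases.  The stimulating electrode is a conducting disk on the surface of a
semi-infinite homogeneous medium (monopolar return at infinity); its
potential field is the analytic equipotential-disk solution, evaluated
quasi-statically, so per-compartment potentials are unit-current scale
factors multiplied by the instantaneous stimulus current.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class PulseTrain:
    """Symmetric charge-balanced biphasic pulse train (cathodic first).

    Within each period: ``-amplitude`` for ``pulse_width`` ms, zero for
    ``ipg`` ms, ``+amplitude`` for ``pulse_width`` ms, then zero until the
    period ends.
    """

    amplitude: float  # uA, phase magnitude
    pulse_width: float  # ms per phase
    frequency: float  # Hz
    duration: float  # ms
    ipg: float = 0.0  # ms
    polarity: str = "cathodic_first"

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude is a magnitude (>= 0); polarity is separate")
        if self.pulse_width <= 0:
            raise ValueError("pulse_width must be > 0")
        if self.ipg < 0:
            raise ValueError("ipg must be >= 0")
        if self.frequency <= 0:
            raise ValueError("frequency must be > 0")
        if self.polarity not in ("cathodic_first", "anodic_first"):
            raise ValueError(f"unknown polarity {self.polarity!r}")
        if 2.0 * self.pulse_width + self.ipg > self.period + 1e-12:
            raise ValueError("2*pulse_width + ipg exceeds the stimulus period")
        if self.duration + 1e-9 < self.period:
            raise ValueError("duration must cover at least one period")

    @property
    def period(self) -> float:
        """ms between pulse onsets."""
        return 1000.0 / self.frequency

    @property
    def n_periods(self) -> int:
        return int(round(self.duration / self.period))

    def pulse_onsets(self) -> np.ndarray:
        """Cathodic-phase onset times (ms) within the train duration."""
        return np.arange(self.n_periods) * self.period

    def current(self, t) -> np.ndarray | float:
        """Instantaneous electrode current (uA) at time(s) t (ms)."""
        t = np.asarray(t, dtype=float)
        phase = np.mod(t, self.period)
        first = -self.amplitude if self.polarity == "cathodic_first" else self.amplitude
        out = np.zeros_like(phase)
        out[phase < self.pulse_width] = first
        second_start = self.pulse_width + self.ipg
        out[(phase >= second_start) & (phase < second_start + self.pulse_width)] = -first
        out[t >= self.duration] = 0.0
        out[t < 0] = 0.0
        return out if out.ndim else float(out)


def waveform_current(t, train: PulseTrain):
    """Electrode current (uA) of the train at time(s) t (ms)."""
    return train.current(t)


def charge_per_phase(train: PulseTrain) -> float:
    """Charge delivered in one phase, nC (uA * ms = nC)."""
    return train.amplitude * train.pulse_width


@dataclass
class ElectrodeModel:
    """Disk electrode on the surface of a semi-infinite homogeneous medium."""

    radius: float = 100.0  # um
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    medium_conductivity: float = 0.1  # S/m
    distance_to_soma: float = 50.0  # um, on-axis standoff of the cell body

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be > 0")
        if self.medium_conductivity <= 0:
            raise ValueError("medium_conductivity must be > 0")


def disk_potential(radial, depth, I: float, electrode: ElectrodeModel):
    """Extracellular potential (mV) of the disk at cylinder coords (r, z) um.

    Equipotential-disk solution in a half space:
    ``V(r, z) = I/(4 sigma a) * (2/pi) * arcsin(2a / (sqrt((r-a)^2+z^2) + sqrt((r+a)^2+z^2)))``.
    On the disk surface (r <= a, z = 0) this reduces to ``I/(4 sigma a)``.
    """
    a_m = electrode.radius * 1e-6
    sigma = electrode.medium_conductivity
    r = np.asarray(radial, dtype=float) * 1e-6
    z = np.abs(np.asarray(depth, dtype=float)) * 1e-6
    a = a_m
    s = np.sqrt((r - a) ** 2 + z ** 2) + np.sqrt((r + a) ** 2 + z ** 2)
    arg = np.clip(2.0 * a / s, -1.0, 1.0)
    v_volts = (I * 1e-6) / (4.0 * sigma * a) * (2.0 / np.pi) * np.arcsin(arg)
    v_mV = v_volts * 1e3
    return v_mV if v_mV.ndim else float(v_mV)


def map_extracellular(compartment_xyz: np.ndarray, electrode: ElectrodeModel) -> np.ndarray:
    """Unit-current extracellular potential (mV per uA) at each compartment.

    ``compartment_xyz`` is (n, 3) in um, in the electrode frame (the disk lies
    in the plane z = electrode.center[2], centered on electrode.center).  The
    time course at compartment i is ``scale[i] * waveform_current(t)``
    (quasi-static coupling).
    """
    xyz = np.atleast_2d(np.asarray(compartment_xyz, dtype=float))
    cx, cy, cz = electrode.center
    r = np.hypot(xyz[:, 0] - cx, xyz[:, 1] - cy)
    z = xyz[:, 2] - cz
    inside = (np.abs(z) < 1e-9) & (r <= electrode.radius)
    if np.any(inside):
        raise ValueError("compartment lies inside the electrode disk")
    return np.asarray(disk_potential(r, z, 1.0, electrode), dtype=float)
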