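"""The stimulation experiment suite.

All protocols follow the same convention: the working current for a given
(pulse width, interphase gap) is the minimum amplitude achieving 100% spike
probability at 120 Hz (one spike per delivered pulse), found by a doubling
bracket plus bisection on a resolution grid.  Frequency-response sweeps then
re-test each tuned current at 200 Hz and report the D1 - A2 firing-rate
difference, the quantity behind selective activation.  Rate-vs-amplitude
curves, 50%-probability saturation windows, channel-swap experiments,
paired-pulse refractory measurement and the depolarizing-sag measurement
complete the suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .cell import CellModel
from .engine import CompiledCell, SimResult, SolverSettings, spike_metrics
from .stim import ElectrodeModel, PulseTrain

DEFAULT_TRAIN_MS = 1000.0
TUNE_FREQ_HZ = 120.0
TEST_FREQ_HZ = 200.0


def default_settings(pulse_width: float) -> SolverSettings:
    """dt 0.01 ms, refined to 0.005 ms for the shortest (0.1 ms) pulses."""
    return SolverSettings(dt=0.005 if pulse_width < 0.2 else 0.01)


@dataclass
class ThresholdResult:
    current: float  # uA
    charge: float  # nC per phase
    achieved_probability: float
    search_trace: list[tuple[float, float]] = field(default_factory=list)
    pulse_width: float = 0.0
    ipg: float = 0.0
    frequency: float = 0.0


@dataclass
class ResponseCurve:
    amplitudes: np.ndarray  # uA
    firing_rates: np.ndarray  # Hz
    spike_probabilities: np.ndarray
    context: dict = field(default_factory=dict)


@dataclass
class SweepResult:
    values: np.ndarray  # swept PW or IPG, ms
    a2_current: np.ndarray  # tuned currents, uA
    d1_current: np.ndarray
    a2_rate: np.ndarray  # Hz at the test frequency
    d1_rate: np.ndarray
    context: dict = field(default_factory=dict)

    @property
    def rate_difference(self) -> np.ndarray:
        """D1 - A2 (positive = D1 more responsive)."""
        return self.d1_rate - self.a2_rate


class NotExcitable(RuntimeError):
    """No amplitude below the bracket cap reached the target probability."""


# ---------------------------------------------------------------------------
# probability / rate


def spike_probability(spike_times, train: PulseTrain) -> float:
    """Spikes per delivered pulse, counting at most one spike per period."""
    n = train.n_periods
    if n == 0:
        raise ValueError("train covers zero periods")
    spike_times = np.asarray(spike_times, dtype=float)
    periods = np.floor(spike_times / train.period).astype(int)
    periods = periods[(periods >= 0) & (periods < n)]
    return len(np.unique(periods)) / n


def firing_rate(spike_times, duration_ms: float) -> float:
    """Detected spikes per second of train."""
    return len(spike_times) / (duration_ms / 1000.0)


# ---------------------------------------------------------------------------
# threshold search


def _probability_at(
    compiled: CompiledCell,
    amplitude: float,
    pulse_width: float,
    ipg: float,
    frequency: float,
    duration: float,
    settings: SolverSettings,
) -> tuple[float, SimResult]:
    train = PulseTrain(amplitude=amplitude, pulse_width=pulse_width,
                       frequency=frequency, duration=duration, ipg=ipg)
    res = compiled.run(train, settings)
    return spike_probability(res.spike_times, train), res


def find_threshold(
    cell: CellModel | CompiledCell,
    pulse_width: float,
    ipg: float = 0.0,
    frequency: float = TUNE_FREQ_HZ,
    target: float = 1.0,
    resolution: float = 1.0,
    electrode: Optional[ElectrodeModel] = None,
    duration: float = DEFAULT_TRAIN_MS,
    settings: Optional[SolverSettings] = None,
    amp_start: float = 1.0,
    amp_cap: float = 20000.0,
    method: str = "bisect",
) -> ThresholdResult:
    """Minimum amplitude (on the resolution grid) achieving the target spike
    probability.

    ``method='bisect'`` brackets by amplitude doubling then bisects;
    ``method='scan'`` is the exhaustive ascending scan at the same
    resolution (the independent check).  Both return the smallest grid
    amplitude achieving the target, with the minimality certificate that the
    next-lower grid point fails it.
    """
    compiled = cell if isinstance(cell, CompiledCell) else CompiledCell(
        cell, electrode or ElectrodeModel())
    settings = settings or default_settings(pulse_width)
    trace: list[tuple[float, float]] = []

    def prob(a: float) -> float:
        p, _ = _probability_at(compiled, a, pulse_width, ipg, frequency,
                               duration, settings)
        trace.append((a, p))
        return p

    if method == "scan":
        a = resolution * max(1, math.ceil(amp_start / resolution))
        while a <= amp_cap:
            p = prob(a)
            if p >= target:
                return ThresholdResult(a, a * pulse_width, p, trace,
                                       pulse_width, ipg, frequency)
            a += resolution
        raise NotExcitable(f"no amplitude <= {amp_cap} uA reached probability {target}")

    # doubling bracket
    lo, hi = 0.0, amp_start
    p_hi = prob(hi)
    while p_hi < target:
        lo = hi
        hi *= 2.0
        if hi > amp_cap:
            raise NotExcitable(
                f"no amplitude <= {amp_cap} uA reached probability {target}")
        p_hi = prob(hi)
    # bisect down to the resolution grid
    while hi - lo > resolution:
        mid = (lo + hi) / 2.0
        if prob(mid) >= target:
            hi = mid
        else:
            lo = mid
    # snap up to the grid and certify minimality
    a = resolution * math.ceil(hi / resolution - 1e-9)
    p = prob(a)
    while p < target:
        a += resolution
        if a > amp_cap:
            raise NotExcitable(
                f"no amplitude <= {amp_cap} uA reached probability {target}")
        p = prob(a)
    while a - resolution > 0:
        p_below = prob(a - resolution)
        if p_below < target:
            break
        a -= resolution
        p = p_below
    return ThresholdResult(a, a * pulse_width, p, trace, pulse_width, ipg, frequency)


# ---------------------------------------------------------------------------
# sweeps


def _rate_at(
    compiled: CompiledCell,
    amplitude: float,
    pulse_width: float,
    ipg: float,
    frequency: float,
    duration: float,
    settings: SolverSettings,
) -> tuple[float, float]:
    """(capped firing rate Hz, spike probability) at one amplitude."""
    train = PulseTrain(amplitude=amplitude, pulse_width=pulse_width,
                       frequency=frequency, duration=duration, ipg=ipg)
    res = compiled.run(train, settings)
    p = spike_probability(res.spike_times, train)
    return p * frequency, p


def strength_duration_sweep(
    cell_a2: CellModel | CompiledCell,
    cell_d1: CellModel | CompiledCell,
    pw_grid: Sequence[float] = (0.1, 0.2, 0.3, 0.6, 1.0, 1.2),
    ipg: float = 0.0,
    tune_frequency: float = TUNE_FREQ_HZ,
    test_frequency: float = TEST_FREQ_HZ,
    electrode: Optional[ElectrodeModel] = None,
    duration: float = DEFAULT_TRAIN_MS,
    resolution: float = 1.0,
) -> SweepResult:
    """Tuned current per pulse width (100% at 120 Hz), rates at 200 Hz."""
    if len(pw_grid) == 0:
        raise ValueError("empty pulse-width grid")
    electrode = electrode or ElectrodeModel()
    ca = cell_a2 if isinstance(cell_a2, CompiledCell) else CompiledCell(cell_a2, electrode)
    cd = cell_d1 if isinstance(cell_d1, CompiledCell) else CompiledCell(cell_d1, electrode)
    currents = {id(ca): [], id(cd): []}
    rates = {id(ca): [], id(cd): []}
    for compiled in (ca, cd):
        amp_start = 1.0
        for pw in pw_grid:
            settings = default_settings(pw)
            thr = find_threshold(compiled, pw, ipg, tune_frequency,
                                 duration=duration, resolution=resolution,
                                 settings=settings, amp_start=amp_start)
            # warm-start the next (longer) pulse width: thresholds decrease
            amp_start = max(resolution, thr.current / 4.0)
            rate, _ = _rate_at(compiled, thr.current, pw, ipg, test_frequency,
                               duration, settings)
            currents[id(compiled)].append(thr.current)
            rates[id(compiled)].append(rate)
    return SweepResult(
        values=np.asarray(pw_grid, dtype=float),
        a2_current=np.asarray(currents[id(ca)]),
        d1_current=np.asarray(currents[id(cd)]),
        a2_rate=np.asarray(rates[id(ca)]),
        d1_rate=np.asarray(rates[id(cd)]),
        context={"swept": "pulse_width", "ipg_ms": ipg,
                 "tune_hz": tune_frequency, "test_hz": test_frequency,
                 "duration_ms": duration},
    )


def ipg_sweep(
    cell_a2: CellModel | CompiledCell,
    cell_d1: CellModel | CompiledCell,
    ipg_grid: Sequence[float] = (0.0, 0.1, 0.2, 0.5, 1.0),
    pulse_width: float = 0.5,
    tune_frequency: float = TUNE_FREQ_HZ,
    test_frequency: float = TEST_FREQ_HZ,
    electrode: Optional[ElectrodeModel] = None,
    duration: float = DEFAULT_TRAIN_MS,
    resolution: float = 1.0,
) -> SweepResult:
    """Tuned current per interphase gap at fixed pulse width, rates at 200 Hz."""
    if len(ipg_grid) == 0:
        raise ValueError("empty IPG grid")
    electrode = electrode or ElectrodeModel()
    ca = cell_a2 if isinstance(cell_a2, CompiledCell) else CompiledCell(cell_a2, electrode)
    cd = cell_d1 if isinstance(cell_d1, CompiledCell) else CompiledCell(cell_d1, electrode)
    settings = default_settings(pulse_width)
    currents = {id(ca): [], id(cd): []}
    rates = {id(ca): [], id(cd): []}
    for compiled in (ca, cd):
        amp_start = 1.0
        for ipg in ipg_grid:
            thr = find_threshold(compiled, pulse_width, ipg, tune_frequency,
                                 duration=duration, resolution=resolution,
                                 settings=settings, amp_start=amp_start)
            amp_start = max(resolution, thr.current / 4.0)
            rate, _ = _rate_at(compiled, thr.current, pulse_width, ipg,
                               test_frequency, duration, settings)
            currents[id(compiled)].append(thr.current)
            rates[id(compiled)].append(rate)
    return SweepResult(
        values=np.asarray(ipg_grid, dtype=float),
        a2_current=np.asarray(currents[id(ca)]),
        d1_current=np.asarray(currents[id(cd)]),
        a2_rate=np.asarray(rates[id(ca)]),
        d1_rate=np.asarray(rates[id(cd)]),
        context={"swept": "ipg", "pw_ms": pulse_width,
                 "tune_hz": tune_frequency, "test_hz": test_frequency,
                 "duration_ms": duration},
    )


# ---------------------------------------------------------------------------
# response curves


def rate_vs_amplitude(
    cell: CellModel | CompiledCell,
    amplitude_range: tuple[float, float],
    pulse_width: float,
    ipg: float = 0.0,
    frequency: float = TEST_FREQ_HZ,
    step: float = 5.0,
    electrode: Optional[ElectrodeModel] = None,
    duration: float = DEFAULT_TRAIN_MS,
    settings: Optional[SolverSettings] = None,
) -> ResponseCurve:
    """Firing rate and spike probability on an amplitude grid (default 5 uA)."""
    lo, hi = amplitude_range
    n = (hi - lo) / step
    if abs(n - round(n)) > 1e-9:
        raise ValueError("amplitude range must be aligned to the step")
    amps = lo + step * np.arange(int(round(n)) + 1)
    compiled = cell if isinstance(cell, CompiledCell) else CompiledCell(
        cell, electrode or ElectrodeModel())
    settings = settings or default_settings(pulse_width)
    rates = np.empty_like(amps)
    probs = np.empty_like(amps)
    for i, a in enumerate(amps):
        rates[i], probs[i] = _rate_at(compiled, a, pulse_width, ipg,
                                      frequency, duration, settings)
    return ResponseCurve(
        amplitudes=amps, firing_rates=rates, spike_probabilities=probs,
        context={"label": compiled.cell.label, "pw_ms": pulse_width,
                 "ipg_ms": ipg, "freq_hz": frequency, "duration_ms": duration},
    )


def saturation_window(
    curve: ResponseCurve, level: float = 0.5, tolerance: float = 0.02
) -> dict:
    """Widest contiguous amplitude interval with probability within
    ``level +/- tolerance``; width 0 if none."""
    if len(curve.amplitudes) == 0:
        raise ValueError("empty curve")
    inside = np.abs(curve.spike_probabilities - level) <= tolerance
    best = (0.0, None)
    i = 0
    n = len(inside)
    while i < n:
        if inside[i]:
            j = i
            while j + 1 < n and inside[j + 1]:
                j += 1
            width = curve.amplitudes[j] - curve.amplitudes[i]
            if width > best[0]:
                best = (width, (float(curve.amplitudes[i]), float(curve.amplitudes[j])))
            i = j + 1
        else:
            i += 1
    return {"width": float(best[0]), "interval": best[1]}


def differential_response(curve_a: ResponseCurve, curve_b: ResponseCurve,
                          target_rate: float = 20.0) -> dict:
    """Per-amplitude rate difference (B - A) and the amplitude gap to reach a
    target rate (first amplitude reaching it in A minus that in B; positive
    when B reaches it at a lower current)."""
    if len(curve_a.amplitudes) == len(curve_b.amplitudes) and \
            np.allclose(curve_a.amplitudes, curve_b.amplitudes):
        amps = curve_a.amplitudes
        ra, rb = curve_a.firing_rates, curve_b.firing_rates
    else:
        amps = np.union1d(curve_a.amplitudes, curve_b.amplitudes)
        amps = amps[(amps >= max(curve_a.amplitudes.min(), curve_b.amplitudes.min())) &
                    (amps <= min(curve_a.amplitudes.max(), curve_b.amplitudes.max()))]
        ra = np.interp(amps, curve_a.amplitudes, curve_a.firing_rates)
        rb = np.interp(amps, curve_b.amplitudes, curve_b.firing_rates)

    def first_reaching(rates: np.ndarray) -> Optional[float]:
        idx = np.flatnonzero(rates >= target_rate)
        return float(amps[idx[0]]) if len(idx) else None

    a_first, b_first = first_reaching(ra), first_reaching(rb)
    gap = None if (a_first is None or b_first is None) else b_first - a_first
    return {
        "amplitudes": amps,
        "difference": rb - ra,
        "target_rate": target_rate,
        "first_amplitude_a": a_first,
        "first_amplitude_b": b_first,
        "amplitude_gap": gap,
    }


# ---------------------------------------------------------------------------
# biophysics experiments


def channel_swap_experiment(
    base: CellModel,
    region: str,
    channel: str,
    target_value: float,
    train: Optional[PulseTrain] = None,
    electrode: Optional[ElectrodeModel] = None,
    i_inject_nA: Optional[np.ndarray] = None,
    duration: Optional[float] = None,
    settings: Optional[SolverSettings] = None,
) -> dict:
    """Run identical stimulation on the base model and on a copy with one
    maximum conductance replaced; report traces and spike-metric deltas."""
    swapped = base.with_density(region, channel, target_value)
    settings = settings or SolverSettings()
    results = {}
    for name, cell in (("base", base), ("swapped", swapped)):
        compiled = CompiledCell(cell, electrode)
        res = compiled.run(train, settings, duration=duration,
                           i_inject_nA=i_inject_nA)
        results[name] = res
    out = {"base": results["base"], "swapped": results["swapped"],
           "region": region, "channel": channel, "target_value": target_value}
    try:
        mb_ = spike_metrics(results["base"].soma_voltage, results["base"].time, settings)
        ms_ = spike_metrics(results["swapped"].soma_voltage, results["swapped"].time, settings)
        out["metrics_base"] = mb_
        out["metrics_swapped"] = ms_
        out["deltas"] = {k: ms_[k] - mb_[k] for k in mb_}
    except ValueError:
        out["deltas"] = None
    return out


def measure_refractory(
    cell: CellModel | CompiledCell,
    pulse_width: float = 0.5,
    ipg: float = 0.0,
    electrode: Optional[ElectrodeModel] = None,
    amplitude: Optional[float] = None,
    interval_range: tuple[float, float] = (1.0, 50.0),
    resolution: float = 0.5,
    settings: Optional[SolverSettings] = None,
    method: str = "bisect",
) -> float:
    """Paired-pulse refractory period (ms).

    Two identical extracellular biphasic pulses at 1.5x the single-pulse
    threshold (unless an amplitude is given); returns the minimal
    inter-pulse interval at which the second pulse elicits a spike, on the
    resolution grid.
    """
    compiled = cell if isinstance(cell, CompiledCell) else CompiledCell(
        cell, electrode or ElectrodeModel())
    settings = settings or default_settings(pulse_width)
    if amplitude is None:
        # single-pulse threshold: one period of a slow train
        thr = find_threshold(compiled, pulse_width, ipg, frequency=10.0,
                             duration=100.0, settings=settings, resolution=1.0)
        amplitude = 1.5 * thr.current

    def spikes_with_gap(interval: float) -> int:
        duration = interval + 40.0
        train = PairedPulse(amplitude, pulse_width, ipg, interval, duration)
        res = compiled.run(train, settings, duration=duration)
        return len(res.spike_times)

    grid = np.arange(interval_range[0], interval_range[1] + resolution / 2.0,
                     resolution)
    if method == "scan":
        for iv in grid:
            if spikes_with_gap(float(iv)) >= 2:
                return float(iv)
        raise NotExcitable("second spike never elicited in the search range")
    lo, hi = 0, len(grid) - 1
    if spikes_with_gap(float(grid[hi])) < 2:
        raise NotExcitable("second spike never elicited in the search range")
    if spikes_with_gap(float(grid[lo])) >= 2:
        return float(grid[lo])
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if spikes_with_gap(float(grid[mid])) >= 2:
            hi = mid
        else:
            lo = mid
    return float(grid[hi])


class PairedPulse:
    """Two identical biphasic pulses separated by an onset-to-onset interval.

    Quacks like a PulseTrain for the engine (provides ``current`` and
    ``duration``).
    """

    def __init__(self, amplitude: float, pulse_width: float, ipg: float,
                 interval: float, duration: float):
        self.amplitude = amplitude
        self.pulse_width = pulse_width
        self.ipg = ipg
        self.interval = interval
        self.duration = duration
        self.frequency = 0.0

    def current(self, t):
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        for onset in (0.0, self.interval):
            ph = t - onset
            out[(ph >= 0) & (ph < self.pulse_width)] = -self.amplitude
            a0 = self.pulse_width + self.ipg
            out[(ph >= a0) & (ph < a0 + self.pulse_width)] = self.amplitude
        return out


def measure_sag(
    cell: CellModel | CompiledCell,
    step_nA: float = -0.005,
    duration: float = 800.0,
    onset: float = 100.0,
    settings: Optional[SolverSettings] = None,
) -> float:
    """Depolarizing sag (mV) during an intracellular hyperpolarizing step:
    V(end of step) - V(peak hyperpolarization); >= 0 with h current present."""
    if step_nA >= 0:
        raise ValueError("step must be hyperpolarizing (negative)")
    if duration < 500.0:
        raise ValueError("step duration must be >= 500 ms")
    compiled = cell if isinstance(cell, CompiledCell) else CompiledCell(cell, None)
    settings = settings or SolverSettings(dt=0.025)
    total = onset + duration + 100.0
    n_steps = int(round(total / settings.dt))
    tmid = (np.arange(n_steps) + 0.5) * settings.dt
    inj = np.where((tmid >= onset) & (tmid < onset + duration), step_nA, 0.0)
    res = compiled.run(None, settings, duration=total, i_inject_nA=inj)
    in_step = (res.time >= onset) & (res.time <= onset + duration)
    v = res.soma_voltage[in_step]
    v_min = float(np.min(v))
    v_end = float(v[-1])
    return v_end - v_min
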