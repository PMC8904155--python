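import numpy as np
import pytest

import rgcsim as rs
from rgcsim.protocols import (
    ResponseCurve,
    default_settings,
    differential_response,
    saturation_window,
    spike_probability,
)
from .conftest import TRAIN_MS, soma_only_cell


def train_at(freq=120.0, duration=TRAIN_MS, **kw):
    defaults = dict(amplitude=50.0, pulse_width=0.5, ipg=0.0)
    defaults.update(kw)
    return rs.PulseTrain(frequency=freq, duration=duration, **defaults)


class TestSpikeProbability:
    def test_one_spike_per_period_is_unity(self):
        t = train_at(duration=1000.0)
        spikes = t.pulse_onsets() + 0.4
        assert spike_probability(spikes, t) == 1.0

    def test_no_spikes_is_zero(self):
        assert spike_probability([], train_at()) == 0.0

    def test_alternating_periods_give_half(self):
        t = train_at(duration=1000.0)
        spikes = t.pulse_onsets()[::2] + 0.4
        assert spike_probability(spikes, t) == 0.5

    def test_multiple_spikes_in_one_period_count_once(self):
        t = train_at(duration=1000.0)
        spikes = np.concatenate([t.pulse_onsets() + 0.4, t.pulse_onsets() + 2.4])
        assert spike_probability(spikes, t) == 1.0


class TestThresholdSearch:
    def test_bisection_agrees_with_exhaustive_scan(self, compiled_pair):
        a2, _ = compiled_pair
        s = default_settings(0.5)
        kw = dict(frequency=120.0, duration=TRAIN_MS, resolution=5.0, settings=s)
        bis = rs.find_threshold(a2, 0.5, method="bisect", **kw)
        scan = rs.find_threshold(a2, 0.5, method="scan", **kw)
        assert bis.current == scan.current

    def test_minimality_certificate(self, compiled_pair):
        """The returned current achieves the target; one resolution step
        below does not."""
        from rgcsim.protocols import _probability_at
        a2, _ = compiled_pair
        s = default_settings(0.5)
        thr = rs.find_threshold(a2, 0.5, frequency=120.0, duration=TRAIN_MS,
                                resolution=5.0, settings=s)
        assert thr.achieved_probability >= 1.0
        below, _ = _probability_at(a2, thr.current - 5.0, 0.5, 0.0, 120.0,
                                   TRAIN_MS, s)
        assert below < 1.0

    def test_non_excitable_reported(self, electrode):
        cell = soma_only_cell("A2", 20.0)  # single compartment: no gradient
        with pytest.raises(rs.NotExcitable):
            rs.find_threshold(cell, 0.5, electrode=electrode, duration=TRAIN_MS,
                              amp_cap=500.0)


class TestStrengthDurationSweep:
    def test_tuned_current_non_increasing_in_pulse_width(self, pw_sweep):
        for c in (pw_sweep.a2_current, pw_sweep.d1_current):
            assert np.all(np.diff(c) <= 0.0)

    def test_long_pulse_threshold_below_short(self, pw_sweep):
        assert pw_sweep.a2_current[-1] <= pw_sweep.a2_current[0]
        assert pw_sweep.d1_current[-1] <= pw_sweep.d1_current[0]

    def test_tuned_current_achieves_target_at_tune_frequency(self, compiled_pair,
                                                             pw_sweep):
        a2, _ = compiled_pair
        from rgcsim.protocols import _probability_at
        s = default_settings(0.3)
        p, _ = _probability_at(a2, float(pw_sweep.a2_current[1]), 0.3, 0.0,
                               120.0, TRAIN_MS, s)
        assert p == 1.0

    def test_difference_sign_convention_is_d1_minus_a2(self, pw_sweep):
        assert np.allclose(pw_sweep.rate_difference,
                           pw_sweep.d1_rate - pw_sweep.a2_rate)


class TestIpgSweep:
    def test_tuned_current_non_increasing_in_gap(self, ipg_sweep_result):
        for c in (ipg_sweep_result.a2_current, ipg_sweep_result.d1_current):
            assert np.all(np.diff(c) <= 0.0)

    def test_zero_gap_entry_matches_strength_duration_protocol(self, compiled_pair):
        """The IPG = 0 entry of the gap sweep and a PW = 0.5 ms threshold
        search are the same computation."""
        a2, _ = compiled_pair
        s = default_settings(0.5)
        thr = rs.find_threshold(a2, 0.5, ipg=0.0, frequency=120.0,
                                duration=TRAIN_MS, resolution=1.0, settings=s)
        sweep = rs.ipg_sweep(a2, a2, ipg_grid=(0.0,), pulse_width=0.5,
                             duration=TRAIN_MS, resolution=1.0)
        assert sweep.a2_current[0] == thr.current


class TestRateVsAmplitude:
    def test_grid_size_and_rate_cap(self, compiled_pair):
        a2, _ = compiled_pair
        curve = rs.rate_vs_amplitude(a2, (20.0, 60.0), 0.5, frequency=200.0,
                                     step=5.0, duration=TRAIN_MS)
        assert len(curve.amplitudes) == int((60 - 20) / 5) + 1
        assert np.all(curve.firing_rates <= 200.0 + 1e-9)
        assert np.all((curve.spike_probabilities >= 0)
                      & (curve.spike_probabilities <= 1))

    def test_misaligned_range_rejected(self, compiled_pair):
        a2, _ = compiled_pair
        with pytest.raises(ValueError):
            rs.rate_vs_amplitude(a2, (20.0, 33.0), 0.5, step=5.0)


class TestSaturationWindow:
    @staticmethod
    def curve(probs, step=5.0):
        amps = np.arange(len(probs)) * step
        probs = np.asarray(probs, dtype=float)
        return ResponseCurve(amps, probs * 200.0, probs)

    def test_flat_half_probability_plateau_measured_exactly(self):
        c = self.curve([0.0, 0.1, 0.5, 0.5, 0.5, 0.5, 1.0])
        w = saturation_window(c, 0.5)
        assert w["width"] == pytest.approx(15.0)
        assert w["interval"] == (10.0, 25.0)

    def test_strictly_increasing_curve_has_zero_window(self):
        c = self.curve(np.linspace(0.0, 1.0, 21))
        assert saturation_window(c, 0.5)["width"] == 0.0

    def test_widest_of_multiple_plateaus_wins(self):
        c = self.curve([0.5, 0.2, 0.5, 0.5, 0.5, 1.0])
        assert saturation_window(c, 0.5)["interval"] == (10.0, 20.0)


class TestDifferentialResponse:
    @staticmethod
    def curve(rates, start=0.0, step=5.0):
        rates = np.asarray(rates, dtype=float)
        amps = start + np.arange(len(rates)) * step
        return ResponseCurve(amps, rates, rates / 200.0)

    def test_identical_curves_have_zero_difference_and_gap(self):
        a = self.curve([0, 10, 50, 200])
        out = differential_response(a, a)
        assert np.all(out["difference"] == 0.0)
        assert out["amplitude_gap"] == 0.0

    def test_antisymmetry(self):
        a = self.curve([0, 10, 50, 200])
        b = self.curve([0, 40, 120, 200])
        ab = differential_response(a, b)
        ba = differential_response(b, a)
        assert np.allclose(ab["difference"], -ba["difference"])
        assert ab["amplitude_gap"] == -ba["amplitude_gap"]

    def test_unreached_target_reported_as_none(self):
        a = self.curve([0, 5, 10, 15])
        out = differential_response(a, a, target_rate=100.0)
        assert out["amplitude_gap"] is None


class TestChannelSwap:
    def test_swap_to_identical_value_is_bit_identical(self, reduced_pair, electrode):
        a2, _ = reduced_pair
        train = train_at(duration=100.0, amplitude=50.0)
        out = rs.channel_swap_experiment(
            a2, "soma", "g_Ca", a2.densities.get("soma", "g_Ca"),
            train=train, electrode=electrode)
        assert np.array_equal(out["base"].soma_voltage,
                              out["swapped"].soma_voltage)


class TestSag:
    def test_passive_cell_shows_no_sag(self):
        from .conftest import passive_cell
        assert rs.measure_sag(passive_cell(20.0)) == pytest.approx(0.0, abs=1e-3)

    def test_sag_grows_with_h_conductance(self):
        base = soma_only_cell("A2", 20.0)
        sags = [rs.measure_sag(base.with_density("soma", "g_h", g))
                for g in (0.0, 1e-4, 2e-4)]
        assert sags[0] < sags[1] < sags[2]

    def test_d1_sag_exceeds_a2_sag(self):
        a2 = soma_only_cell("A2", 20.0)
        d1 = soma_only_cell("D1", 12.0)
        assert rs.measure_sag(d1) > rs.measure_sag(a2)

    def test_depolarizing_step_rejected(self):
        with pytest.raises(ValueError):
            rs.measure_sag(soma_only_cell("A2", 20.0), step_nA=0.01)
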