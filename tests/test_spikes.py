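"""Spike detection, evoked-AP counting, shape metrics, holding-current QC."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import synaptoprobe as sp
from synaptoprobe.spikes import (count_total_evoked, detect_spikes,
                                 measure_first_spike_shape, qc_holding)
from synaptoprobe.traces import AnalysisError


def _flat_trace(level=-60.0, n=8000, dt=0.05):
    return sp.Trace(np.full(n, level), dt, "voltage")


class TestDetectSpikes:
    def test_flat_trace_detects_nothing(self):
        assert detect_spikes(_flat_trace()) == []

    def test_requires_voltage_trace(self):
        with pytest.raises(TypeError):
            detect_spikes(sp.Trace(np.zeros(100), 0.05, "current"))

    def test_template_spikes_found_at_peaks(self, noiseless_cc):
        rec, gt = noiseless_cc
        window = rec.protocol.step_window
        for i in (20, 30):
            det = detect_spikes(rec.sweeps[i][1], window)
            truth = gt.spike_peak_times[i]
            assert len(det) == len(truth)
            assert np.max(np.abs(np.array(det) - truth)) <= rec.dt + 1e-9

    def test_refractory_merges_twin_peaks(self):
        """Two peaks 1 ms apart with a 2 ms refractory count once."""
        dt = 0.05
        v = np.full(4000, -60.0)
        p = sp.SpikeParams(fall_ms=0.3, ahp_plateau_ms=0.2, recover_ms=0.3)
        t = np.arange(4000) * dt
        for onset in (100.0, 101.0):
            m = (t >= onset) & (t <= onset + p.width_ms(-60.0))
            v[m] = np.maximum(v[m], p.waveform(t[m] - onset, -60.0))
        det = detect_spikes(sp.Trace(v, dt, "voltage"))
        assert len(det) == 1

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(offset=st.floats(-10.0, 10.0), shift=st.integers(-1, 1))
    def test_count_invariant_to_offset_and_shift(self, offset, shift,
                                                 noiseless_cc):
        rec, gt = noiseless_cc
        tr = rec.sweeps[20][1]
        v = np.roll(tr.samples, shift) + offset
        n = len(detect_spikes(sp.Trace(v, tr.dt, "voltage"),
                              rec.protocol.step_window))
        assert n == gt.spikes_per_step[20]


class TestCountTotalEvoked:
    def test_sums_only_first_17_steps(self, noiseless_cc):
        rec, gt = noiseless_cc
        assert count_total_evoked(rec) == gt.spikes_per_step[:17].sum()
        assert count_total_evoked(rec, count_steps=35) == \
            gt.spikes_per_step.sum()

    def test_spikes_beyond_window_excluded(self):
        """A neuron spiking only above step 17 counts zero."""
        rec, gt = sp.gen_current_clamp(rheobase_pa=40.0, f_i_gain=0.3, seed=0)
        assert gt.spikes_per_step[:17].sum() == 0
        assert gt.spikes_per_step.sum() > 0
        assert count_total_evoked(rec) == 0

    def test_too_few_sweeps_is_an_error(self, noiseless_cc):
        rec, _ = noiseless_cc
        short = sp.Recording(cell_id="x", group_label="", mode="current_clamp",
                             sweeps=rec.sweeps[:5], protocol=rec.protocol)
        with pytest.raises(AnalysisError):
            count_total_evoked(short)

    def test_exact_recovery_with_noise(self):
        ok = 0
        for seed in range(25):
            rec, gt = sp.gen_current_clamp(seed=seed, noise_sd_mv=2.0)
            ok += count_total_evoked(rec) == gt.spikes_per_step[:17].sum()
        assert ok == 25


class TestSpikeShape:
    def test_closed_form_template_recovered(self, noiseless_cc):
        rec, gt = noiseless_cc
        s = measure_first_spike_shape(rec)
        p = gt.spike_params
        assert s.threshold == pytest.approx(p.threshold_mv, abs=0.5)
        assert s.amplitude == pytest.approx(p.amplitude_mv, abs=1.0)
        assert s.width_fwhm == pytest.approx(p.fwhm(), abs=2 * rec.dt)
        assert s.fast_ahp == pytest.approx(p.fast_ahp(), abs=0.5)

    def test_plateau_ahp_measured_on_plateau(self):
        p = sp.SpikeParams(ahp_mv=-8.0, ahp_plateau_ms=8.0)
        rec, _ = sp.gen_current_clamp(spike_params=p, seed=0)
        s = measure_first_spike_shape(rec)
        assert s.fast_ahp == pytest.approx(-8.0, abs=0.5)

    @pytest.mark.parametrize("rise", [0.5, 1.0, 1.5, 2.0])
    def test_threshold_within_one_sample_over_rise_times(self, rise):
        p = sp.SpikeParams(rise_ms=rise)
        rec, _ = sp.gen_current_clamp(spike_params=p, seed=0)
        s = measure_first_spike_shape(rec)
        # 1 sample of the foot's end slope bounds the voltage error
        slope = p.foot_slope_frac * p.amplitude_mv / p.rise_ms
        assert abs(s.threshold - p.threshold_mv) <= slope * rec.dt + 1e-6

    def test_no_spike_is_an_error(self):
        rec, _ = sp.gen_current_clamp(f_i_gain=0.0, seed=0)
        with pytest.raises(AnalysisError):
            measure_first_spike_shape(rec)

    def test_symmetric_template_fwhm_invariant_under_time_reversal(self):
        """A mirror-symmetric spike measures identically in reversed time."""
        dt = 0.05
        base, thr, amp, foot, rise = -60.0, -40.0, 70.0, 2.0, 1.0
        t = np.arange(12000) * dt
        v = np.full(t.size, base)
        onset, total = 200.0, 2 * foot + 2 * rise
        x = t - onset
        m = (x >= 0) & (x < foot)
        v[m] = base + (thr - base) * (x[m] / foot) ** 3
        m = (x >= foot) & (x < foot + rise)
        v[m] = thr + amp * (x[m] - foot) / rise
        m = (x >= foot + rise) & (x < foot + 2 * rise)
        v[m] = thr + amp * (foot + 2 * rise - x[m]) / rise
        m = (x >= foot + 2 * rise) & (x <= total)
        v[m] = base + (thr - base) * ((total - x[m]) / foot) ** 3
        s_fwd = sp.measure_spike_shape(sp.Trace(v, dt, "voltage"))
        s_rev = sp.measure_spike_shape(sp.Trace(v[::-1].copy(), dt, "voltage"))
        assert s_fwd.width_fwhm == pytest.approx(s_rev.width_fwhm, abs=2 * dt)
        assert s_fwd.amplitude == pytest.approx(s_rev.amplitude, abs=1.0)
        assert s_fwd.width_fwhm == pytest.approx(rise, abs=2 * dt)


class TestQCHolding:
    @pytest.mark.parametrize("holding,passed", [(-30.0, True), (-51.0, False),
                                                (50.0, True), (-50.0, True),
                                                (50.1, False)])
    def test_50pa_rule_is_strict(self, holding, passed):
        rec, _ = sp.gen_current_clamp(seed=0, holding_pa=holding)
        assert qc_holding(rec).passed is passed

    def test_holding_measured_from_command_baseline(self):
        rec, _ = sp.gen_current_clamp(seed=0, holding_pa=-33.0)
        rec.metadata.pop("holding_pa")
        r = qc_holding(rec)
        assert r.passed is True
        assert r.holding_current == pytest.approx(-33.0, abs=0.5)

    def test_unavailable_holding_is_indeterminate(self):
        rec, _ = sp.gen_epsc_trace(rate=0.5, duration=2.0, seed=0)
        r = qc_holding(rec)
        assert r.passed is None and r.reasons
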