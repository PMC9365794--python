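"""Generator correctness: closed forms, inventories, reproducibility."""

import numpy as np
import pytest

import synaptoprobe as sp
from synaptoprobe.synth import epsc_kernel, vc_model_current


class TestEpscGenerator:
    def test_zero_rate_gives_pure_noise(self):
        rec, gt = sp.gen_epsc_trace(rate=0.0, noise_sd=2.0, duration=5.0, seed=3)
        assert gt.event_times.size == 0
        x = rec.sweeps[0][1].samples
        assert abs(np.mean(x)) < 0.2 and abs(np.std(x) - 2.0) < 0.2

    def test_poisson_event_counts(self):
        """Over 500 seeds the mean count obeys the Poisson law (rate·T)."""
        rate, dur = 1.0, 60.0
        counts = [sp.gen_epsc_trace(rate=rate, duration=dur, noise_sd=0,
                                    seed=s)[1].event_times.size
                  for s in range(500)]
        mean = np.mean(counts)
        assert abs(mean - rate * dur) <= 3 * np.sqrt(rate * dur / 500)

    def test_noiseless_single_event_amplitude(self):
        rec, gt = sp.gen_epsc_trace(rate=0.05, amp_cv=0.0, amp_mean=20.0,
                                    noise_sd=0.0, tau=2.0, duration=60.0,
                                    seed=8)
        assert gt.event_times.size >= 1
        x = rec.sweeps[0][1].samples
        i0 = int(round(gt.event_times[0] / 0.05))
        assert x[i0] == pytest.approx(-20.0, abs=1e-9)

    def test_inventory_matches_trace_reproducibly(self):
        a = sp.gen_epsc_trace(rate=2.0, duration=10.0, seed=42)
        b = sp.gen_epsc_trace(rate=2.0, duration=10.0, seed=42)
        assert np.array_equal(a[0].sweeps[0][1].samples,
                              b[0].sweeps[0][1].samples)
        assert np.array_equal(a[1].event_times, b[1].event_times)
        assert a[1].event_times.size == a[1].event_amplitudes.size
        assert np.all(np.diff(a[1].event_times) >= 0)
        assert np.all(a[1].event_times < 10_000.0)

    @pytest.mark.parametrize("kw", [dict(duration=-1), dict(dt=0),
                                    dict(amp_cv=-0.1), dict(amp_mean=0)])
    def test_parameter_errors(self, kw):
        with pytest.raises(ValueError):
            sp.gen_epsc_trace(rate=1.0, **kw)

    def test_kernel_is_unit_inward_exponential(self):
        k = epsc_kernel(2.0, 0.05)
        assert k[0] == -1.0
        assert np.allclose(k, -np.exp(-np.arange(k.size) * 0.05 / 2.0))


class TestCurrentClampGenerator:
    def test_zero_gain_is_spike_free(self):
        rec, gt = sp.gen_current_clamp(f_i_gain=0.0, seed=0)
        assert gt.spikes_per_step.sum() == 0

    def test_command_levels_follow_protocol(self):
        """Step i commands holding − 12 + 3·i pA."""
        rec, _ = sp.gen_current_clamp(seed=0, holding_pa=-20.0)
        proto = rec.protocol
        assert proto.n_steps == 35 and proto.increment == 3.0
        for i, (cmd, _) in enumerate(rec.sweeps):
            on, off = proto.step_window
            mid = cmd.slice(on + 1, off - 1).samples
            assert np.allclose(mid, -20.0 - 12.0 + 3.0 * i)

    def test_triangular_template_fwhm_closed_form(self):
        """Rise 1 ms to +60 mV, fall 2 ms to threshold: FWHM = 1.5 ms."""
        p = sp.SpikeParams(amplitude_mv=60.0, rise_ms=1.0, fall_ms=2.0,
                           ahp_mv=0.0, threshold_mv=-30.0)
        assert p.fwhm() == pytest.approx(1.5)

    def test_ground_truth_counts_match_fi_rule(self):
        rec, gt = sp.gen_current_clamp(f_i_gain=0.2, rheobase_pa=9.0, seed=1)
        from synaptoprobe.synth import spikes_for_current
        expected = [spikes_for_current(i, 0.2, 9.0)
                    for i in rec.protocol.relative_levels()]
        assert list(gt.spikes_per_step) == expected

    def test_template_wider_than_step_rejected(self):
        p = sp.SpikeParams(ahp_plateau_ms=500.0)
        with pytest.raises(ValueError, match="wider"):
            sp.gen_current_clamp(spike_params=p)


class TestVoltageClampGenerator:
    def test_leak_only_is_ohmic(self):
        rec, gt = sp.gen_voltage_clamp_iv(na_gmax=0, kfast_gmax=0,
                                          kslow_gmax=0, leak_conductance=1.0,
                                          capacitance=20.0, noise_sd=0)
        i = np.argmin(np.abs(gt.step_voltages - (-40.0)))  # +20 mV from hold
        _, resp = rec.sweeps[i]
        on, off = rec.protocol.step_window
        seg = resp.slice(on + 1, off - 1).samples
        assert np.allclose(seg, 20.0)
        assert gt.kslow_density[i] == pytest.approx(1.0)

    def test_na_peak_at_most_negative_model_step(self):
        """Detected most-negative step matches the closed-form model."""
        rec, gt = sp.gen_voltage_clamp_iv(kfast_gmax=0, kslow_gmax=0,
                                          leak_conductance=0, noise_sd=0)
        t = np.linspace(0, 10, 2001)
        analytic = [vc_model_current(t, v, -60.0, 10.0, 0, 0, 0).min()
                    for v in gt.step_voltages]
        assert (np.argmin(gt.na_peak_density) == np.argmin(analytic))

    def test_density_is_peak_over_capacitance(self):
        rec, gt = sp.gen_voltage_clamp_iv(capacitance=20.0, noise_sd=0)
        iv = sp.extract_iv_curves(rec, 20.0)
        assert np.allclose(iv.na_peak_density, gt.na_peak_density, rtol=1e-6)


class TestMembraneTestGenerator:
    def test_transient_tau_is_rc(self):
        rec, _ = sp.gen_membrane_test(capacitance=30.0, resistance=500.0,
                                      noise_sd=0)
        cmd, cur = rec.sweeps[0]
        base_ms = rec.metadata["baseline_ms"]
        i_on = cur.index_at(base_ms)
        plateau = cur.samples[-100:].mean()
        trans = cur.samples[i_on:] - plateau
        # amplitude falls to 1/e of its initial value after τ = RC = 15 ms
        i_tau = int(round(15.0 / cur.dt))
        assert trans[i_tau] == pytest.approx(trans[0] / np.e, rel=1e-3)

    def test_zero_step_is_flat(self):
        rec, _ = sp.gen_membrane_test(step_mv=0.0, noise_sd=0)
        assert np.allclose(rec.sweeps[0][1].samples, 0.0)

    def test_transient_charge_equals_c_dv(self):
        """∫(I − plateau)dt = C·ΔV = −100 fC for C=20 pF, ΔV=−5 mV."""
        rec, _ = sp.gen_membrane_test(capacitance=20.0, resistance=500.0,
                                      step_mv=-5.0, noise_sd=0)
        cur = rec.sweeps[0][1]
        i_on = cur.index_at(rec.metadata["baseline_ms"])
        plateau = cur.samples[-200:].mean()
        q = np.sum(cur.samples[i_on:] - plateau) * cur.dt
        assert q == pytest.approx(-100.0, rel=0.01)


class TestCohort:
    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            sp.CohortConfig(groups=[sp.GroupSpec(name="only", n_neurons=3)])

    def test_zero_neuron_group_rejected(self):
        with pytest.raises(ValueError):
            sp.GroupSpec(name="empty", n_neurons=0)

    def test_reproducible_and_complete(self):
        cfg = sp.CohortConfig.two_group_demo(n_per_group=2, seed=5)
        for g in cfg.groups:
            g.epsc_duration_s = 5.0
        b1, t1 = sp.gen_cohort(cfg)
        b2, t2 = sp.gen_cohort(cfg)
        assert len(b1) == 4 and t1.shape[0] == 4
        assert np.array_equal(b1[0].epsc.sweeps[0][1].samples,
                              b2[0].epsc.sweeps[0][1].samples)
        assert list(t1["cell_id"]) == list(t2["cell_id"])
        assert set(t1["group_label"]) == {"control", "PD"}
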