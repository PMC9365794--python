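"""Group statistics: Welch t, Fisher exact, ANOVA, summary tables."""

import math

import numpy as np
import pytest
from scipy.stats import fisher_exact

import synaptoprobe as sp
from synaptoprobe.events import EventSummary
from synaptoprobe.stats import welch_t


def _neuron(cell_id, group, rate=None, active=None, evoked=None,
            na_min=None):
    f = sp.NeuronFeatures(cell_id=cell_id, group_label=group)
    if rate is not None or active is not None:
        n = int(round((rate or 0.0) * 60))
        f.epsc = EventSummary(n_events=n, duration=60.0, rate=rate or 0.0,
                              mean_amplitude=20.0,
                              amplitude_ecdf=np.array([20.0] * max(n, 1)),
                              mean_decay_tau=2.0,
                              active=bool(active) if active is not None
                              else n > 20)
    if evoked is not None:
        f.total_evoked_ap = evoked
    if na_min is not None:
        f.iv = sp.IVCurves(step_voltages=np.array([-20.0]),
                           na_peak_density=np.array([na_min]),
                           kfast_density=np.array([1.0]),
                           kslow_density=np.array([1.0]),
                           capacitance_used=20.0)
    return f


def fisher_p_bruteforce(a, b, c, d):
    """Two-tailed Fisher p by full hypergeometric enumeration."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def log_prob(k):
        return (math.lgamma(r1 + 1) - math.lgamma(k + 1)
                - math.lgamma(r1 - k + 1)
                + math.lgamma(r2 + 1) - math.lgamma(c1 - k + 1)
                - math.lgamma(r2 - c1 + k + 1)
                + math.lgamma(c1 + 1) + math.lgamma(n - c1 + 1)
                - math.lgamma(n + 1))

    lo, hi = max(0, c1 - r2), min(r1, c1)
    probs = {k: math.exp(log_prob(k)) for k in range(lo, hi + 1)}
    p_obs = probs[a]
    return min(sum(p for p in probs.values() if p <= p_obs * (1 + 1e-9)), 1.0)


class TestCompareFeature:
    def test_identical_groups_t_zero(self):
        feats = [_neuron(f"a{i}", "A", rate=v) for i, v in
                 enumerate([1.0, 2.0, 3.0])]
        feats += [_neuron(f"b{i}", "B", rate=v) for i, v in
                  enumerate([1.0, 2.0, 3.0])]
        c = sp.compare_feature(feats, "epsc.rate", "A", "B")
        assert c.statistic == pytest.approx(0.0, abs=1e-12)
        assert c.p_value == pytest.approx(1.0)
        assert c.sem_a == pytest.approx(np.std([1, 2, 3], ddof=1) / np.sqrt(3))

    def test_symmetry_under_group_swap(self):
        rng = np.random.default_rng(3)
        feats = [_neuron(f"a{i}", "A", rate=r)
                 for i, r in enumerate(rng.lognormal(0, 0.5, 8))]
        feats += [_neuron(f"b{i}", "B", rate=r)
                  for i, r in enumerate(rng.lognormal(-1, 0.5, 8))]
        ab = sp.compare_feature(feats, "epsc.rate", "A", "B")
        ba = sp.compare_feature(feats, "epsc.rate", "B", "A")
        assert ab.statistic == pytest.approx(-ba.statistic)
        assert ab.p_value == pytest.approx(ba.p_value)

    def test_single_neuron_group_errors_by_name(self):
        feats = [_neuron("a0", "A", rate=1.0), _neuron("a1", "A", rate=2.0),
                 _neuron("b0", "B", rate=1.0)]
        with pytest.raises(ValueError, match="'B'"):
            sp.compare_feature(feats, "epsc.rate", "A", "B")

    def test_qc_failed_neurons_excluded(self):
        feats = [_neuron(f"a{i}", "A", rate=1.0 + i) for i in range(3)]
        feats += [_neuron(f"b{i}", "B", rate=1.0 + i) for i in range(3)]
        bad = _neuron("a_bad", "A", rate=100.0)
        bad.qc = sp.QCResult(holding_current=-80.0, passed=False,
                             reasons=["holding"])
        c = sp.compare_feature(feats + [bad], "epsc.rate", "A", "B")
        assert c.n_a == 3  # outlier was QC-excluded


class TestActiveFraction:
    def test_all_active_both_groups_p1(self):
        feats = [_neuron(f"a{i}", "A", rate=1.0, active=True)
                 for i in range(10)]
        feats += [_neuron(f"b{i}", "B", rate=1.0, active=True)
                  for i in range(10)]
        c = sp.compare_active_fraction(feats, "A", "B")
        assert c.p_value == pytest.approx(1.0)

    def test_fisher_matches_bruteforce_on_spec_table(self):
        """[[10,0],[2,8]] two-tailed Fisher p by full enumeration."""
        feats = [_neuron(f"a{i}", "A", rate=1.0, active=True)
                 for i in range(10)]
        feats += [_neuron(f"b{i}", "B", rate=1.0, active=i < 2)
                  for i in range(10)]
        c = sp.compare_active_fraction(feats, "A", "B")
        assert c.extra["table"] == [[10, 0], [2, 8]]
        assert c.p_value == pytest.approx(fisher_p_bruteforce(10, 0, 2, 8),
                                          rel=1e-9)

    def test_fisher_oracle_random_tables(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            a, b, c, d = rng.integers(0, 16, size=4)
            if (a + b == 0) or (c + d == 0):
                continue
            _, p = fisher_exact([[a, b], [c, d]])
            assert p == pytest.approx(fisher_p_bruteforce(a, b, c, d),
                                      rel=1e-8, abs=1e-12)

    def test_empty_group_rejected(self):
        feats = [_neuron("a0", "A", rate=1.0, active=True)]
        with pytest.raises(ValueError):
            sp.compare_active_fraction(feats, "A", "B")


class TestAnova:
    def test_duplicated_group_f_near_zero(self):
        vals = [-10.0, -12.0, -14.0, -16.0]
        feats = [_neuron(f"a{i}", "A", na_min=v) for i, v in enumerate(vals)]
        feats += [_neuron(f"b{i}", "B", na_min=v) for i, v in enumerate(vals)]
        c = sp.iv_family_anova(feats, "na", ["A", "B"])
        assert c.statistic == pytest.approx(0.0, abs=1e-12)

    def test_scaled_group_detected(self):
        rng = np.random.default_rng(7)
        feats = [_neuron(f"a{i}", "A", na_min=v)
                 for i, v in enumerate(rng.normal(-16, 2, 15))]
        feats += [_neuron(f"b{i}", "B", na_min=v)
                  for i, v in enumerate(rng.normal(-4, 1, 15))]
        c = sp.iv_family_anova(feats, "na", ["A", "B"])
        assert c.p_value < 1e-6

    def test_missing_group_data_rejected(self):
        feats = [_neuron("a0", "A", na_min=-10.0),
                 _neuron("a1", "A", na_min=-12.0),
                 _neuron("b0", "B", rate=1.0)]
        with pytest.raises(ValueError):
            sp.iv_family_anova(feats, "na", ["A", "B"])


class TestGroupTable:
    def test_two_group_table_complete(self):
        feats = [_neuron(f"a{i}", "A", rate=1.0 + 0.1 * i, evoked=10 + i)
                 for i in range(15)]
        feats += [_neuron(f"b{i}", "B", rate=0.2 + 0.02 * i, evoked=5 + i)
                  for i in range(15)]
        t = sp.build_group_table(feats)
        assert len(t) == 2
        assert set(t["group"]) == {"A", "B"}
        assert t.loc[t.group == "A", "epsc_rate_hz_n"].item() == 15
        a_mean = t.loc[t.group == "A", "epsc_rate_hz_mean"].item()
        assert a_mean == pytest.approx(np.mean([1.0 + 0.1 * i
                                                for i in range(15)]))

    def test_group_without_epsc_data_has_empty_columns(self):
        feats = [_neuron(f"a{i}", "A", rate=1.0) for i in range(3)]
        feats += [_neuron(f"b{i}", "B", evoked=4) for i in range(3)]
        t = sp.build_group_table(feats)
        b = t[t.group == "B"].iloc[0]
        assert b["n_epsc"] == 0
        assert np.isnan(b["epsc_rate_hz_mean"])


class TestWelchKernel:
    def test_type_one_error_calibrated(self):
        """Null Welch t on lognormal cohorts rejects ≈ 5% at α = 0.05."""
        rng = np.random.default_rng(12)
        rejections = 0
        n_rep = 500
        for _ in range(n_rep):
            a = rng.lognormal(0.0, 0.7, 15)
            b = rng.lognormal(0.0, 0.7, 15)
            _, p = welch_t(a, b)
            rejections += p < 0.05
        assert 0.03 <= rejections / n_rep <= 0.07
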