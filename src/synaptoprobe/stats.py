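"""Group-level aggregation and statistics over per-neuron features.

The default two-group comparison is a two-tailed Welch t-test (the
"two-sample t-test" of the study, read as unequal-variance; a pooled
Student's t is available behind a flag).  Active-fraction comparisons use
Fisher's exact test on the 2×2 active/inactive table.  Current-density
families are compared with a one-way ANOVA on each neuron's extreme density
(most negative Na across steps; largest K); a per-voltage two-way layout is
available as an alternative.  No multiple-testing correction is applied;
reports annotate the number of tests performed instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .events import EventSummary
from .passive import PassiveProps
from .spikes import QCResult, SpikeShape
from .voltage_clamp import IVCurves

__all__ = ["NeuronFeatures", "GroupComparison", "compare_feature",
           "compare_active_fraction", "iv_family_anova", "build_group_table",
           "features_to_frame", "welch_t"]


@dataclass
class NeuronFeatures:
    """Every per-neuron quantity the pipeline extracts."""

    cell_id: str
    group_label: str
    qc: QCResult | None = None
    total_evoked_ap: int | None = None
    spike_shape: SpikeShape | None = None
    passive: PassiveProps | None = None
    iv: IVCurves | None = None
    epsc: EventSummary | None = None

    @property
    def qc_passed(self) -> bool:
        return bool(self.qc and self.qc.passed)


@dataclass
class GroupComparison:
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    mean_a: float | None
    mean_b: float | None
    sem_a: float | None
    sem_b: float | None
    test: str
    statistic: float
    p_value: float
    extra: dict = field(default_factory=dict)


_FEATURE_GETTERS = {
    "total_evoked_ap": lambda f: f.total_evoked_ap,
    "spike_shape.threshold": lambda f: f.spike_shape.threshold if f.spike_shape else None,
    "spike_shape.amplitude": lambda f: f.spike_shape.amplitude if f.spike_shape else None,
    "spike_shape.width_fwhm": lambda f: f.spike_shape.width_fwhm if f.spike_shape else None,
    "spike_shape.fast_ahp": lambda f: f.spike_shape.fast_ahp if f.spike_shape else None,
    "passive.input_conductance": lambda f: f.passive.input_conductance if f.passive else None,
    "passive.capacitance": lambda f: f.passive.capacitance if f.passive else None,
    "epsc.rate": lambda f: f.epsc.rate if f.epsc else None,
    "epsc.mean_amplitude": lambda f: f.epsc.mean_amplitude if f.epsc else None,
    "epsc.mean_decay_tau": lambda f: f.epsc.mean_decay_tau if f.epsc else None,
    "iv.na_peak_min": lambda f: float(np.min(f.iv.na_peak_density)) if f.iv else None,
    "iv.kfast_max": lambda f: float(np.max(f.iv.kfast_density)) if f.iv else None,
    "iv.kslow_max": lambda f: float(np.max(f.iv.kslow_density)) if f.iv else None,
}


def feature_values(features: list[NeuronFeatures], feature_path: str,
                   group: str, qc_only: bool = True) -> np.ndarray:
    """Non-missing values of one feature for QC-passed neurons of a group."""
    getter = _FEATURE_GETTERS.get(feature_path)
    if getter is None:
        raise KeyError(f"unknown feature path {feature_path!r}; "
                       f"known: {sorted(_FEATURE_GETTERS)}")
    vals = []
    for f in features:
        if f.group_label != group:
            continue
        if qc_only and f.qc is not None and not f.qc_passed:
            continue
        v = getter(f)
        if v is not None and np.isfinite(v):
            vals.append(float(v))
    return np.asarray(vals)


def welch_t(a: np.ndarray, b: np.ndarray,
            equal_var: bool = False) -> tuple[float, float]:
    """Two-tailed two-sample t; Welch by default."""
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    return float(res.statistic), float(res.pvalue)


def _sem(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1) / np.sqrt(x.size))


def compare_feature(features: list[NeuronFeatures], feature_path: str,
                    group_a: str, group_b: str,
                    equal_var: bool = False) -> GroupComparison:
    """Two-tailed t comparison of one feature between two groups.

    Missing values are excluded (and reflected in the reported n); fewer
    than 2 values in either group is an error naming that group.
    """
    a = feature_values(features, feature_path, group_a)
    b = feature_values(features, feature_path, group_b)
    for name, x in ((group_a, a), (group_b, b)):
        if x.size < 2:
            raise ValueError(f"group {name!r} has {x.size} non-missing "
                             f"value(s) for {feature_path}; need ≥ 2")
    t, p = welch_t(a, b, equal_var=equal_var)
    return GroupComparison(
        group_a=group_a, group_b=group_b, n_a=a.size, n_b=b.size,
        mean_a=float(a.mean()), mean_b=float(b.mean()),
        sem_a=_sem(a), sem_b=_sem(b),
        test="student_t" if equal_var else "welch_t",
        statistic=t, p_value=p, extra={"feature": feature_path})


def compare_active_fraction(features: list[NeuronFeatures], group_a: str,
                            group_b: str, test: str = "fisher_exact",
                            ) -> GroupComparison:
    """Compare the fraction of synaptically active neurons between groups.

    Builds the 2×2 active/inactive table over QC-passed neurons with EPSC
    data and applies Fisher's exact two-tailed test (chi-square behind the
    ``test`` flag).
    """
    def table_row(group):
        act = inact = 0
        for f in features:
            if f.group_label != group or f.epsc is None:
                continue
            if f.qc is not None and not f.qc_passed:
                continue
            if f.epsc.active:
                act += 1
            else:
                inact += 1
        return act, inact

    a_act, a_in = table_row(group_a)
    b_act, b_in = table_row(group_b)
    if a_act + a_in == 0 or b_act + b_in == 0:
        raise ValueError("both groups need at least one neuron with EPSC data")
    table = np.array([[a_act, a_in], [b_act, b_in]])
    if test == "fisher_exact":
        stat, p = sps.fisher_exact(table, alternative="two-sided")
    elif test == "chi2":
        stat, p = sps.chi2_contingency(table, correction=True)[:2]
    else:
        raise ValueError(f"unknown test {test!r}")
    return GroupComparison(
        group_a=group_a, group_b=group_b, n_a=a_act + a_in, n_b=b_act + b_in,
        mean_a=a_act / (a_act + a_in), mean_b=b_act / (b_act + b_in),
        sem_a=None, sem_b=None, test=test, statistic=float(stat),
        p_value=float(p), extra={"table": table.tolist()})


def iv_family_anova(features: list[NeuronFeatures], component: str,
                    groups: list[str], per_voltage: bool = False,
                    ) -> GroupComparison:
    """ANOVA over current densities across ≥2 groups.

    Default: one-way ANOVA on each neuron's extreme density of the chosen
    component (Na: most negative across steps; K: largest).  With
    ``per_voltage=True`` a two-way layout (group × step voltage, no
    interaction) is used instead and the group main-effect F is reported.
    """
    path = {"na": "iv.na_peak_min", "kfast": "iv.kfast_max",
            "kslow": "iv.kslow_max"}.get(component)
    if path is None:
        raise ValueError(f"unknown component {component!r}")
    if len(groups) < 2:
        raise ValueError("need at least two groups")

    if not per_voltage:
        samples = []
        for g in groups:
            x = feature_values(features, path, g)
            if x.size < 2:
                raise ValueError(f"group {g!r} has fewer than 2 neurons with I–V data")
            samples.append(x)
        f_stat, p = sps.f_oneway(*samples)
        ns = [s.size for s in samples]
        return GroupComparison(
            group_a=groups[0], group_b=groups[-1], n_a=ns[0], n_b=ns[-1],
            mean_a=float(samples[0].mean()), mean_b=float(samples[-1].mean()),
            sem_a=_sem(samples[0]), sem_b=_sem(samples[-1]),
            test="anova_oneway", statistic=float(f_stat), p_value=float(p),
            extra={"groups": groups, "n_per_group": ns, "component": component})

    attr = {"na": "na_peak_density", "kfast": "kfast_density",
            "kslow": "kslow_density"}[component]
    rows = []
    for f in features:
        if f.group_label not in groups or f.iv is None:
            continue
        if f.qc is not None and not f.qc_passed:
            continue
        for v, d in zip(f.iv.step_voltages, getattr(f.iv, attr)):
            rows.append((f.group_label, float(v), float(d)))
    if not rows:
        raise ValueError("no I–V data in the requested groups")
    df = pd.DataFrame(rows, columns=["group", "voltage", "density"])
    # two-way additive ANOVA via explicit sums of squares on a balanced grid
    grand = df["density"].mean()
    ss_group = sum(len(sub) * (sub["density"].mean() - grand) ** 2
                   for _, sub in df.groupby("group"))
    ss_volt = sum(len(sub) * (sub["density"].mean() - grand) ** 2
                  for _, sub in df.groupby("voltage"))
    ss_tot = float(((df["density"] - grand) ** 2).sum())
    df_group = df["group"].nunique() - 1
    df_volt = df["voltage"].nunique() - 1
    df_res = len(df) - 1 - df_group - df_volt
    ss_res = ss_tot - ss_group - ss_volt
    f_stat = (ss_group / df_group) / (ss_res / df_res)
    p = float(sps.f.sf(f_stat, df_group, df_res))
    counts = df.groupby("group").size()
    return GroupComparison(
        group_a=groups[0], group_b=groups[-1],
        n_a=int(counts.get(groups[0], 0)), n_b=int(counts.get(groups[-1], 0)),
        mean_a=None, mean_b=None, sem_a=None, sem_b=None,
        test="anova_twoway_group_voltage", statistic=float(f_stat),
        p_value=p, extra={"groups": groups, "component": component})


def features_to_frame(features: list[NeuronFeatures]) -> pd.DataFrame:
    """Flatten per-neuron features into a tidy table (one row per neuron).

    Missing metrics become NaN (written as empty CSV fields, never 0).
    """
    rows = []
    for f in features:
        s, p, e = f.spike_shape, f.passive, f.epsc
        rows.append({
            "cell_id": f.cell_id,
            "group": f.group_label,
            "qc_passed": f.qc.passed if f.qc else None,
            "holding_pa": f.qc.holding_current if f.qc else np.nan,
            "total_evoked_ap": f.total_evoked_ap,
            "spike_threshold_mv": s.threshold if s else np.nan,
            "spike_amplitude_mv": s.amplitude if s else np.nan,
            "spike_fwhm_ms": s.width_fwhm if s else np.nan,
            "fast_ahp_mv": (s.fast_ahp if s and s.fast_ahp is not None else np.nan),
            "input_conductance_ns": (p.input_conductance
                                     if p and p.input_conductance is not None else np.nan),
            "capacitance_pf": (p.capacitance
                               if p and p.capacitance is not None else np.nan),
            "na_peak_density_min": (float(np.min(f.iv.na_peak_density))
                                    if f.iv else np.nan),
            "kfast_density_max": (float(np.max(f.iv.kfast_density))
                                  if f.iv else np.nan),
            "kslow_density_max": (float(np.max(f.iv.kslow_density))
                                  if f.iv else np.nan),
            "epsc_rate_hz": e.rate if e else np.nan,
            "epsc_n_events": e.n_events if e else None,
            "epsc_mean_amplitude_pa": (e.mean_amplitude
                                       if e and e.mean_amplitude is not None else np.nan),
            "epsc_mean_tau_ms": (e.mean_decay_tau
                                 if e and e.mean_decay_tau is not None else np.nan),
            "epsc_active": e.active if e else None,
        })
    return pd.DataFrame(rows)


def build_group_table(features: list[NeuronFeatures],
                      groups: list[str] | None = None) -> pd.DataFrame:
    """Per-group n, mean and SEM for every numeric feature + active fraction."""
    df = features_to_frame(features)
    df = df[(df["qc_passed"] != False)]  # noqa: E712 — keep None (indeterminate-included configs)
    if groups is not None:
        df = df[df["group"].isin(groups)]
    numeric = [c for c in df.columns
               if c not in ("cell_id", "group", "qc_passed", "epsc_active",
                            "epsc_n_events")]
    rows = []
    for g, sub in df.groupby("group", sort=True):
        row: dict = {"group": g, "n_neurons": len(sub)}
        for c in numeric:
            x = sub[c].dropna().to_numpy(dtype=float)
            row[f"{c}_n"] = x.size
            row[f"{c}_mean"] = x.mean() if x.size else np.nan
            row[f"{c}_sem"] = (_sem(x) if x.size > 1 else np.nan)
        act = sub["epsc_active"].dropna()
        row["n_epsc"] = int(act.size)
        row["active_fraction"] = float(act.mean()) if act.size else np.nan
        rows.append(row)
    return pd.DataFrame(rows)
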