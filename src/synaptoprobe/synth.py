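"""Synthetic patch-clamp recordings with exact ground truth.

Every generator emulates one of the acquisition protocols used for
iPSC-derived dopaminergic neurons — gap-free voltage-clamp EPSC recordings at
−60 mV, 35-step/3-pA current-clamp excitability families, −90…+80 mV
voltage-step families, and membrane-test sweeps — and returns both the
:class:`~synaptoprobe.traces.Recording` and a :class:`SynthGroundTruth`
carrying the generative parameters and the exact inventory of inserted
events/spikes.  The analysis stages are tested by recovering that inventory.

The spiking model is deliberately a template model, not a conductance ODE:
piecewise-linear spikes have closed-form threshold, amplitude, FWHM and AHP,
which is what makes the shape analysis testable to stated tolerances.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .traces import Recording, StepProtocol, Trace

__all__ = [
    "SpikeParams", "SynthGroundTruth", "GroupSpec", "CohortConfig",
    "NeuronBundle", "gen_epsc_trace", "gen_current_clamp",
    "gen_voltage_clamp_iv", "gen_membrane_test", "gen_cohort",
    "lognormal_params", "DEFAULT_DT_MS",
]

DEFAULT_DT_MS = 0.05          # 20 kHz acquisition
E_NA_MV = 60.0
E_K_MV = -90.0


def lognormal_params(mean: float, cv: float) -> tuple[float, float]:
    """(mu, sigma) of a lognormal with the given arithmetic mean and CV."""
    if mean <= 0:
        raise ValueError("lognormal mean must be positive")
    if cv < 0:
        raise ValueError("CV must be non-negative")
    sigma2 = np.log1p(cv * cv)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, float(np.sqrt(sigma2))


@dataclass
class SpikeParams:
    """Piecewise-linear action-potential template.

    The waveform leaves the (subthreshold) baseline with a slow depolarizing
    foot up to ``threshold_mv``, rises linearly to ``threshold + amplitude``
    in ``rise_ms``, falls linearly to ``threshold + ahp_mv`` in ``fall_ms``,
    holds that afterhyperpolarization plateau for ``ahp_plateau_ms``, and
    relaxes back to baseline over ``recover_ms``.  All shape metrics have
    closed forms (see :meth:`fwhm`).
    """

    threshold_mv: float = -40.0
    amplitude_mv: float = 70.0      # peak above threshold
    rise_ms: float = 1.0
    fall_ms: float = 2.0
    ahp_mv: float = -8.0            # plateau level relative to threshold
    ahp_plateau_ms: float = 8.0
    foot_slope_frac: float = 0.4    # foot end slope / upstroke slope
    recover_ms: float = 5.0

    def __post_init__(self) -> None:
        if self.amplitude_mv <= 0 or self.rise_ms <= 0 or self.fall_ms <= 0:
            raise ValueError("amplitude, rise and fall must be positive")
        if self.ahp_mv > 0:
            raise ValueError("AHP level must be ≤ 0 (relative to threshold)")
        if not 0 < self.foot_slope_frac < 1:
            raise ValueError("foot_slope_frac must lie in (0, 1)")

    def foot_ms(self, baseline_mv: float) -> float:
        """Duration of the cubic depolarizing foot from this baseline.

        Chosen so that the foot joins the upstroke with a slope of
        ``foot_slope_frac`` × the rise slope — the slope must *increase*
        at threshold for the second-derivative criterion to be meaningful.
        Cubic with zero initial slope ⇒ mean slope = end slope / 3.
        """
        dv = self.threshold_mv - baseline_mv
        if dv <= 0:
            raise ValueError("baseline must lie below threshold")
        end_slope = self.foot_slope_frac * self.amplitude_mv / self.rise_ms
        return 3.0 * dv / end_slope

    def width_ms(self, baseline_mv: float) -> float:
        return (self.foot_ms(baseline_mv) + self.rise_ms + self.fall_ms
                + self.ahp_plateau_ms + self.recover_ms)

    def fwhm(self) -> float:
        """Analytic full width at half maximum.

        Half level is threshold + amplitude/2; the rising branch crosses it
        rise/2 after threshold, the falling branch (amplitude → ahp)
        fall·(amplitude/2)/(amplitude − ahp) after the peak.
        """
        a, h = self.amplitude_mv, self.ahp_mv
        return self.rise_ms / 2.0 + self.fall_ms * (a / 2.0) / (a - h)

    def fast_ahp(self) -> float:
        """Analytic fast AHP: V(5 ms after threshold re-crossing) − threshold.

        The falling branch re-crosses threshold fall·a/(a−h) after the peak;
        5 ms later the waveform sits on the AHP plateau provided the plateau
        outlasts the residual fall plus 5 ms, which the defaults guarantee.
        """
        a, h = self.amplitude_mv, self.ahp_mv
        t_recross_after_peak = self.fall_ms * a / (a - h)
        remaining_fall = self.fall_ms - t_recross_after_peak
        if remaining_fall + 5.0 <= remaining_fall + self.ahp_plateau_ms:
            return h
        raise ValueError("AHP plateau too short for the 5 ms measurement")

    def waveform(self, t_rel: np.ndarray, baseline_mv: float) -> np.ndarray:
        """Template voltage at times ``t_rel`` (ms) past its onset.

        The depolarizing foot from baseline to threshold is cubic in time
        (slope and curvature grow monotonically toward threshold, as the
        approach to threshold does in real recordings), so the second
        derivative has a single first maximum exactly at the threshold
        corner; every later segment is linear.
        """
        thr, base = self.threshold_mv, baseline_mv
        n1 = self.foot_ms(base)
        n2 = n1 + self.rise_ms
        n3 = n2 + self.fall_ms
        n4 = n3 + self.ahp_plateau_ms
        n5 = n4 + self.recover_ms
        v = np.full(t_rel.shape, base, dtype=float)
        m = (t_rel >= 0) & (t_rel < n1)
        v[m] = base + (thr - base) * (t_rel[m] / n1) ** 3
        m = (t_rel >= n1) & (t_rel < n2)
        v[m] = thr + self.amplitude_mv * (t_rel[m] - n1) / self.rise_ms
        m = (t_rel >= n2) & (t_rel < n3)
        v[m] = (thr + self.amplitude_mv
                + (self.ahp_mv - self.amplitude_mv) * (t_rel[m] - n2) / self.fall_ms)
        m = (t_rel >= n3) & (t_rel < n4)
        v[m] = thr + self.ahp_mv
        m = (t_rel >= n4) & (t_rel <= n5)
        v[m] = thr + self.ahp_mv + (base - thr - self.ahp_mv) * (t_rel[m] - n4) / self.recover_ms
        return v


@dataclass
class SynthGroundTruth:
    """Generative parameters plus exact inserted-event/spike inventories."""

    seed: int
    group_label: str = ""
    # EPSC recording
    epsc_rate: float | None = None            # events/s
    epsc_amp_mean: float | None = None        # pA
    epsc_amp_cv: float | None = None
    epsc_tau: float | None = None             # ms
    event_times: np.ndarray | None = None     # ms, sorted
    event_amplitudes: np.ndarray | None = None  # pA, magnitudes
    noise_sd: float | None = None             # pA
    # current clamp
    spikes_per_step: np.ndarray | None = None
    spike_params: SpikeParams | None = None
    spike_peak_times: list | None = None      # per sweep, ms
    f_i_gain: float | None = None
    rheobase_pa: float | None = None
    # passive / voltage clamp
    capacitance: float | None = None          # pF
    membrane_resistance: float | None = None  # MΩ
    leak_conductance: float | None = None     # nS
    na_gmax: float | None = None
    kfast_gmax: float | None = None
    kslow_gmax: float | None = None
    step_voltages: np.ndarray | None = None   # mV
    na_peak_density: np.ndarray | None = None   # pA/pF, ≤ 0
    kfast_density: np.ndarray | None = None
    kslow_density: np.ndarray | None = None

    def validate(self, duration_ms: float | None = None) -> None:
        if self.epsc_rate is not None and self.epsc_rate < 0:
            raise ValueError("epsc_rate must be ≥ 0")
        if self.epsc_tau is not None and not self.epsc_tau > 0:
            raise ValueError("epsc_tau must be positive")
        if self.capacitance is not None and not self.capacitance > 0:
            raise ValueError("capacitance must be positive")
        if self.event_times is not None:
            if np.any(np.diff(self.event_times) < 0):
                raise ValueError("event_times must be sorted")
            if duration_ms is not None and self.event_times.size:
                if self.event_times[-1] > duration_ms:
                    raise ValueError("event beyond recording duration")


# ---------------------------------------------------------------------------
# EPSC recordings

def epsc_kernel(tau_ms: float, dt_ms: float, rise_tau_ms: float = 0.0,
                tail: float = 1e-4) -> np.ndarray:
    """Unit-amplitude inward EPSC kernel (negative), truncated at ``tail``.

    Default is instantaneous rise + mono-exponential decay.  A finite-rise
    biexponential (difference of exponentials, renormalized to unit peak) is
    available via ``rise_tau_ms``.
    """
    if rise_tau_ms <= 0:
        n = max(int(np.ceil(-np.log(tail) * tau_ms / dt_ms)), 2)
        t = np.arange(n) * dt_ms
        return -np.exp(-t / tau_ms)
    n = max(int(np.ceil((-np.log(tail) * tau_ms + 5 * rise_tau_ms) / dt_ms)), 2)
    t = np.arange(n) * dt_ms
    k = np.exp(-t / tau_ms) - np.exp(-t / rise_tau_ms)
    return -k / k.max()


def gen_epsc_trace(rate: float, amp_mean: float = 20.0, amp_cv: float = 0.3,
                   tau: float = 2.3, noise_sd: float = 2.0,
                   duration: float = 60.0, dt: float = DEFAULT_DT_MS,
                   seed: int = 0, rise_tau: float = 0.0,
                   cell_id: str = "synth", group_label: str = "",
                   ) -> tuple[Recording, SynthGroundTruth]:
    """Gap-free voltage-clamp EPSC recording at −60 mV command.

    Events are a homogeneous Poisson process of intensity ``rate`` (events/s)
    over ``duration`` (s); each event is an inward deflection with magnitude
    drawn lognormal(mean=``amp_mean`` pA, CV=``amp_cv``) and decay constant
    ``tau`` (ms); overlapping events sum linearly; additive white Gaussian
    noise of SD ``noise_sd`` pA rides on a zero baseline.
    """
    if rate < 0:
        raise ValueError("rate must be ≥ 0")
    if duration <= 0 or dt <= 0:
        raise ValueError("duration and dt must be positive")
    if amp_mean <= 0:
        raise ValueError("amp_mean must be positive")
    if amp_cv < 0:
        raise ValueError("amp_cv must be ≥ 0")

    rng = np.random.default_rng(seed)
    duration_ms = duration * 1000.0
    n = int(round(duration_ms / dt))
    current = np.zeros(n)

    n_events = rng.poisson(rate * duration)
    times = np.sort(rng.uniform(0.0, duration_ms, size=n_events))
    if amp_cv > 0:
        mu, sigma = lognormal_params(amp_mean, amp_cv)
        amps = rng.lognormal(mu, sigma, size=n_events)
    else:
        amps = np.full(n_events, amp_mean)

    kernel = epsc_kernel(tau, dt, rise_tau)
    # events drawn past the last sample are excluded from trace AND inventory
    keep = times < n * dt
    times, amps = times[keep], amps[keep]
    for t_ev, a in zip(times, amps):
        i0 = int(round(t_ev / dt))
        seg = min(kernel.size, n - i0)
        current[i0:i0 + seg] += a * kernel[:seg]
    if noise_sd > 0:
        current += rng.normal(0.0, noise_sd, size=n)

    command = Trace(np.full(n, -60.0), dt, "voltage")
    response = Trace(current, dt, "current")
    rec = Recording(cell_id=cell_id, group_label=group_label,
                    mode="voltage_clamp", sweeps=[(command, response)],
                    protocol=None,
                    metadata={"gap_free": True, "bicuculline_um": 40.0,
                              "holding_mv": -60.0, "duration_s": duration})
    gt = SynthGroundTruth(seed=seed, group_label=group_label, epsc_rate=rate,
                          epsc_amp_mean=amp_mean, epsc_amp_cv=amp_cv,
                          epsc_tau=tau, event_times=times,
                          event_amplitudes=amps, noise_sd=noise_sd)
    gt.validate(duration_ms=duration_ms)
    return rec, gt


# ---------------------------------------------------------------------------
# Current-clamp excitability families

def spikes_for_current(i_rel_pa: float, f_i_gain: float,
                       rheobase_pa: float) -> int:
    """Thresholded-linear F–I rule: 0 below rheobase, else ⌊gain·(I−rheo)⌋."""
    if i_rel_pa < rheobase_pa:
        return 0
    return int(np.floor(f_i_gain * (i_rel_pa - rheobase_pa)))


def gen_current_clamp(protocol: StepProtocol | None = None,
                      spike_params: SpikeParams | None = None,
                      f_i_gain: float = 0.15, rheobase_pa: float = 6.0,
                      seed: int = 0, noise_sd_mv: float = 0.0,
                      rest_mv: float = -60.0, holding_pa: float = -20.0,
                      subthreshold_mv_per_pa: float = 0.15,
                      dt: float = DEFAULT_DT_MS, cell_id: str = "synth",
                      group_label: str = "",
                      ) -> tuple[Recording, SynthGroundTruth]:
    """Current-clamp step family with a deterministic template-spike count.

    Each sweep depolarizes by ``subthreshold_mv_per_pa`` × injected current
    (clipped 10 mV below threshold) and carries ``spikes_for_current`` evenly
    spaced piecewise-linear spikes; spike counts and shape metrics are exact
    ground truth.
    """
    protocol = protocol or StepProtocol.current_clamp_default()
    spike_params = spike_params or SpikeParams()
    if f_i_gain < 0:
        raise ValueError("f_i_gain must be ≥ 0")
    if spike_params.width_ms(rest_mv) > protocol.step_duration:
        raise ValueError("spike template wider than the step")

    rng = np.random.default_rng(seed)
    n = int(round(protocol.sweep_duration / dt))
    t = np.arange(n) * dt
    on, off = protocol.step_window
    in_step = (t >= on) & (t < off)

    sweeps = []
    counts, peak_times_per_sweep = [], []
    for i_rel in protocol.relative_levels():
        baseline = rest_mv + min(subthreshold_mv_per_pa * max(i_rel, 0.0),
                                 spike_params.threshold_mv - rest_mv - 10.0)
        v = np.full(n, rest_mv)
        v[in_step] = baseline
        n_spk = spikes_for_current(i_rel, f_i_gain, rheobase_pa)
        width = spike_params.width_ms(baseline)
        spacing = protocol.step_duration / n_spk if n_spk else np.inf
        if n_spk and spacing < width:
            raise ValueError(
                f"{n_spk} spikes do not fit in the step without overlap")
        peaks = []
        t_peak_rel = spike_params.foot_ms(baseline) + spike_params.rise_ms
        for k in range(n_spk):
            onset = on + (k + 0.5) * spacing - t_peak_rel
            seg = (t >= onset) & (t <= onset + width)
            v[seg] = spike_params.waveform(t[seg] - onset, baseline)
            peaks.append(onset + t_peak_rel)
        if noise_sd_mv > 0:
            v = v + rng.normal(0.0, noise_sd_mv, size=n)
        cmd = np.full(n, holding_pa)
        cmd[in_step] += i_rel
        sweeps.append((Trace(cmd, dt, "current"), Trace(v, dt, "voltage")))
        counts.append(n_spk)
        peak_times_per_sweep.append(peaks)

    rec = Recording(cell_id=cell_id, group_label=group_label,
                    mode="current_clamp", sweeps=sweeps, protocol=protocol,
                    metadata={"holding_pa": holding_pa, "rest_mv": rest_mv})
    gt = SynthGroundTruth(
        seed=seed, group_label=group_label,
        spikes_per_step=np.array(counts, dtype=int),
        spike_params=spike_params, spike_peak_times=peak_times_per_sweep,
        f_i_gain=f_i_gain, rheobase_pa=rheobase_pa)
    return rec, gt


# ---------------------------------------------------------------------------
# Voltage-clamp step families

def _boltzmann(v, v_half, slope):
    return 1.0 / (1.0 + np.exp(-(v - v_half) / slope))


def vc_model_current(t_ms: np.ndarray, v_step: float, v_hold: float,
                     na_gmax: float, kfast_gmax: float, kslow_gmax: float,
                     leak_ns: float,
                     na_vhalf: float = -30.0, na_slope: float = 6.0,
                     na_tau_act: float = 0.4, na_tau_inact: float = 2.0,
                     kf_vhalf: float = -20.0, kf_slope: float = 10.0,
                     kf_tau_act: float = 1.0, kf_tau_inact: float = 80.0,
                     kf_sustained_frac: float = 0.4,
                     ks_vhalf: float = -10.0, ks_slope: float = 12.0,
                     ks_tau_act: float = 25.0) -> np.ndarray:
    """Closed-form step-response current (pA) of the synthetic cell.

    Linear leak referenced to the holding potential, a Boltzmann-gated
    transient inward (Na-like) component with exponential activation and
    inactivation, a fast-activating partially-inactivating outward (fast K)
    component, and a slowly activating sustained outward (slow K) component.
    Evaluated analytically at the given times after step onset.
    """
    leak = leak_ns * (v_step - v_hold)
    m = _boltzmann(v_step, na_vhalf, na_slope)
    i_na = (na_gmax * m * (v_step - E_NA_MV)
            * (1.0 - np.exp(-t_ms / na_tau_act)) * np.exp(-t_ms / na_tau_inact))
    nf = _boltzmann(v_step, kf_vhalf, kf_slope)
    inact = kf_sustained_frac + (1 - kf_sustained_frac) * np.exp(-t_ms / kf_tau_inact)
    i_kf = (kfast_gmax * nf * (v_step - E_K_MV)
            * (1.0 - np.exp(-t_ms / kf_tau_act)) * inact)
    ns_ = _boltzmann(v_step, ks_vhalf, ks_slope)
    i_ks = kslow_gmax * ns_ * (v_step - E_K_MV) * (1.0 - np.exp(-t_ms / ks_tau_act))
    return leak + i_na + i_kf + i_ks


def gen_voltage_clamp_iv(protocol: StepProtocol | None = None,
                         na_gmax: float = 10.0, kfast_gmax: float = 3.0,
                         kslow_gmax: float = 2.0, leak_conductance: float = 1.0,
                         capacitance: float = 20.0, seed: int = 0,
                         noise_sd: float = 0.0, dt: float = DEFAULT_DT_MS,
                         early_ms: float = 10.0, blank_ms: float = 0.5,
                         late_ms: float = 50.0, cell_id: str = "synth",
                         group_label: str = "",
                         ) -> tuple[Recording, SynthGroundTruth]:
    """Voltage-step family (−90…+80 mV from −60 mV hold by default).

    Ground truth holds, per step, the noiseless-model current densities under
    the same operational definitions the extraction applies: Na peak = most
    negative baseline-subtracted current in the blanked early window, fast
    K = its maximum there, slow K = mean over the final ``late_ms`` of the
    step; all divided by capacitance.  The gmax scales are in nS so that
    gmax·(V−E) is pA.
    """
    protocol = protocol or StepProtocol.voltage_clamp_default()
    for g in (na_gmax, kfast_gmax, kslow_gmax, leak_conductance):
        if g < 0:
            raise ValueError("conductance scales must be ≥ 0")
    if capacitance <= 0:
        raise ValueError("capacitance must be positive")

    rng = np.random.default_rng(seed)
    n = int(round(protocol.sweep_duration / dt))
    t = np.arange(n) * dt
    on, off = protocol.step_window
    in_step = (t >= on) & (t < off)
    t_rel = t[in_step] - on
    v_hold = protocol.holding_level

    sweeps = []
    na_d, kf_d, ks_d = [], [], []
    volts = protocol.step_levels()
    early = (t_rel >= blank_ms) & (t_rel < early_ms)
    late = t_rel >= (protocol.step_duration - late_ms)
    for v_step in volts:
        model = vc_model_current(t_rel, v_step, v_hold, na_gmax, kfast_gmax,
                                 kslow_gmax, leak_conductance)
        i = np.zeros(n)
        i[in_step] = model
        na_d.append(min(model[early].min(), 0.0) / capacitance)
        kf_d.append(model[early].max() / capacitance)
        ks_d.append(model[late].mean() / capacitance)
        if noise_sd > 0:
            i = i + rng.normal(0.0, noise_sd, size=n)
        cmd = np.full(n, v_hold)
        cmd[in_step] = v_step
        sweeps.append((Trace(cmd, dt, "voltage"), Trace(i, dt, "current")))

    rec = Recording(cell_id=cell_id, group_label=group_label,
                    mode="voltage_clamp", sweeps=sweeps, protocol=protocol,
                    metadata={"holding_mv": v_hold})
    gt = SynthGroundTruth(
        seed=seed, group_label=group_label, capacitance=capacitance,
        leak_conductance=leak_conductance, na_gmax=na_gmax,
        kfast_gmax=kfast_gmax, kslow_gmax=kslow_gmax, step_voltages=volts,
        na_peak_density=np.array(na_d), kfast_density=np.array(kf_d),
        kslow_density=np.array(ks_d))
    return rec, gt


# ---------------------------------------------------------------------------
# Membrane test

def gen_membrane_test(capacitance: float = 30.0, resistance: float = 500.0,
                      step_mv: float = -5.0, duration: float = 250.0,
                      dt: float = DEFAULT_DT_MS, noise_sd: float = 0.0,
                      seed: int = 0, n_sweeps: int = 1,
                      baseline_ms: float = 20.0, cell_id: str = "synth",
                      group_label: str = "",
                      ) -> tuple[Recording, SynthGroundTruth]:
    """Small-voltage-step membrane test of an ideal RC cell.

    The step response is I(t) = (ΔV/R)·(1 + e^{−t/RC}): an instantaneous
    jump relaxing with τ = R·C to the Ohmic plateau ΔV/R.  The transient
    charge above the plateau integrates to exactly Q = C·ΔV, the quantity
    the charge-integration capacitance estimator recovers.  R in MΩ, C in
    pF, so τ = R·C/1000 ms and ΔV/R is in nA (converted to pA).
    """
    if capacitance <= 0 or resistance <= 0 or duration <= 0 or dt <= 0:
        raise ValueError("capacitance, resistance, duration and dt must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration / dt))
    t = np.arange(n) * dt
    tau_ms = resistance * capacitance / 1000.0
    plateau_pa = step_mv / resistance * 1000.0
    after = t >= baseline_ms
    base_current = np.zeros(n)
    base_current[after] = plateau_pa * (1.0 + np.exp(-(t[after] - baseline_ms) / tau_ms))
    cmd = np.full(n, -60.0)
    cmd[after] += step_mv

    sweeps = []
    for _ in range(n_sweeps):
        i = base_current.copy()
        if noise_sd > 0:
            i += rng.normal(0.0, noise_sd, size=n)
        sweeps.append((Trace(cmd.copy(), dt, "voltage"), Trace(i, dt, "current")))
    rec = Recording(cell_id=cell_id, group_label=group_label,
                    mode="voltage_clamp", sweeps=sweeps, protocol=None,
                    metadata={"membrane_test": True, "step_mv": step_mv,
                              "baseline_ms": baseline_ms, "holding_mv": -60.0})
    gt = SynthGroundTruth(seed=seed, group_label=group_label,
                          capacitance=capacitance,
                          membrane_resistance=resistance, noise_sd=noise_sd)
    return rec, gt


# ---------------------------------------------------------------------------
# Cohorts

@dataclass
class GroupSpec:
    """Per-group generative distributions for a synthetic cohort.

    Rates are lognormal across neurons (right-skewed, as spontaneous event
    rates in culture are); conductance scales and capacitance are normal
    truncated at a small positive floor.  ``rate_scale``-like group effects
    are expressed by setting the means directly.
    """

    name: str
    n_neurons: int
    epsc_rate_mean: float = 1.0        # events/s
    epsc_rate_cv: float = 0.8
    epsc_amp_mean: float = 20.0        # pA
    epsc_amp_cv: float = 0.3
    epsc_tau_ms: float = 2.3
    epsc_duration_s: float = 60.0
    noise_sd_pa: float = 2.0
    f_i_gain: float = 0.15             # spikes/pA above rheobase
    rheobase_pa: float = 6.0
    spike_params: SpikeParams = field(default_factory=SpikeParams)
    spike_threshold_sd_mv: float = 2.0   # per-neuron threshold variability
    voltage_noise_mv: float = 0.5
    na_gmax_mean: float = 10.0
    na_gmax_cv: float = 0.3
    kfast_gmax_mean: float = 3.0
    kfast_gmax_cv: float = 0.3
    kslow_gmax_mean: float = 2.0
    kslow_gmax_cv: float = 0.3
    leak_ns: float = 0.5
    capacitance_mean: float = 25.0
    capacitance_cv: float = 0.2
    membrane_resistance_mohm: float = 1000.0
    vc_noise_sd_pa: float = 5.0

    def __post_init__(self) -> None:
        if self.n_neurons < 1:
            raise ValueError(f"group {self.name!r} must have ≥ 1 neuron")


@dataclass
class CohortConfig:
    groups: list[GroupSpec]
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.groups) < 2:
            raise ValueError("a cohort needs at least 2 groups")
        names = [g.name for g in self.groups]
        if len(set(names)) != len(names):
            raise ValueError("group names must be unique")

    @classmethod
    def two_group_demo(cls, n_per_group: int = 15, seed: int = 0,
                       pd_rate_scale: float = 0.2,
                       pd_tau_ms: float = 1.5) -> "CohortConfig":
        """Control vs PD demo: depressed EPSC rate and faster decay in PD."""
        ctrl = GroupSpec(name="control", n_neurons=n_per_group)
        pd = GroupSpec(name="PD", n_neurons=n_per_group,
                       epsc_rate_mean=ctrl.epsc_rate_mean * pd_rate_scale,
                       epsc_tau_ms=pd_tau_ms)
        return cls(groups=[ctrl, pd], seed=seed)

    @classmethod
    def from_dict(cls, data: dict) -> "CohortConfig":
        valid = {f.name for f in dataclasses.fields(GroupSpec)}
        groups = []
        for g in data.get("groups", []):
            g = dict(g)
            sp = g.pop("spike_params", None)
            unknown = set(g) - valid
            if unknown:
                raise ValueError(f"unknown group key(s): {sorted(unknown)}")
            spec = GroupSpec(**g)
            if sp:
                spec.spike_params = SpikeParams(**sp)
            groups.append(spec)
        return cls(groups=groups, seed=int(data.get("seed", 0)))


@dataclass
class NeuronBundle:
    """All four recordings of one synthetic neuron, plus its ground truth."""

    cell_id: str
    group_label: str
    epsc: Recording
    current_clamp: Recording
    voltage_clamp: Recording
    membrane_test: Recording
    truth: dict


def _truncated_normal(rng, mean, cv, floor_frac=0.05):
    x = rng.normal(mean, cv * mean)
    return max(x, floor_frac * mean)


def gen_cohort(config: CohortConfig, seed: int | None = None,
               ) -> tuple[list[NeuronBundle], pd.DataFrame]:
    """Generate a multi-group cohort of synthetic neurons.

    One root seed is split deterministically per neuron via
    ``numpy.random.SeedSequence.spawn``, so cohorts are exactly reproducible
    and any neuron can be regenerated independently.  Returns the bundles and
    a ground-truth table (one row per neuron).
    """
    root = np.random.SeedSequence(config.seed if seed is None else seed)
    bundles: list[NeuronBundle] = []
    rows = []
    neuron_seqs = root.spawn(sum(g.n_neurons for g in config.groups))
    idx = 0
    for g in config.groups:
        for j in range(g.n_neurons):
            seq = neuron_seqs[idx]
            idx += 1
            rng = np.random.default_rng(seq)
            sub = [int(s.generate_state(1)[0] % (2**31)) for s in seq.spawn(4)]
            cell_id = f"{g.name}_{j:03d}"

            mu, sigma = lognormal_params(g.epsc_rate_mean, g.epsc_rate_cv)
            rate = float(rng.lognormal(mu, sigma))
            cap = _truncated_normal(rng, g.capacitance_mean, g.capacitance_cv)
            na = _truncated_normal(rng, g.na_gmax_mean, g.na_gmax_cv)
            kf = _truncated_normal(rng, g.kfast_gmax_mean, g.kfast_gmax_cv)
            ks = _truncated_normal(rng, g.kslow_gmax_mean, g.kslow_gmax_cv)

            epsc_rec, epsc_gt = gen_epsc_trace(
                rate=rate, amp_mean=g.epsc_amp_mean, amp_cv=g.epsc_amp_cv,
                tau=g.epsc_tau_ms, noise_sd=g.noise_sd_pa,
                duration=g.epsc_duration_s, seed=sub[0], cell_id=cell_id,
                group_label=g.name)
            spike_params = g.spike_params
            if g.spike_threshold_sd_mv > 0:
                spike_params = dataclasses.replace(
                    spike_params, threshold_mv=float(rng.normal(
                        spike_params.threshold_mv, g.spike_threshold_sd_mv)))
            cc_rec, cc_gt = gen_current_clamp(
                spike_params=spike_params, f_i_gain=g.f_i_gain,
                rheobase_pa=g.rheobase_pa, seed=sub[1],
                noise_sd_mv=g.voltage_noise_mv, cell_id=cell_id,
                group_label=g.name)
            vc_rec, vc_gt = gen_voltage_clamp_iv(
                na_gmax=na, kfast_gmax=kf, kslow_gmax=ks,
                leak_conductance=g.leak_ns, capacitance=cap, seed=sub[2],
                noise_sd=g.vc_noise_sd_pa, cell_id=cell_id, group_label=g.name)
            mem_rec, _ = gen_membrane_test(
                capacitance=cap, resistance=g.membrane_resistance_mohm,
                seed=sub[3], noise_sd=2.0, n_sweeps=5, cell_id=cell_id,
                group_label=g.name)

            n_count = int(cc_gt.spikes_per_step[:17].sum())
            truth = {
                "cell_id": cell_id, "group_label": g.name,
                "epsc_rate": rate, "n_events": int(epsc_gt.event_times.size),
                "epsc_tau_ms": g.epsc_tau_ms,
                "epsc_amp_mean": g.epsc_amp_mean,
                "capacitance_pf": cap, "leak_ns": g.leak_ns,
                "na_gmax": na, "kfast_gmax": kf, "kslow_gmax": ks,
                "total_evoked_ap": n_count,
                "na_peak_density_min": float(vc_gt.na_peak_density.min()),
                "threshold_mv": spike_params.threshold_mv,
                "fwhm_ms": spike_params.fwhm(),
                "amplitude_mv": spike_params.amplitude_mv,
                "fast_ahp_mv": spike_params.fast_ahp(),
            }
            bundles.append(NeuronBundle(cell_id, g.name, epsc_rec, cc_rec,
                                        vc_rec, mem_rec, truth))
            rows.append(truth)
    return bundles, pd.DataFrame(rows)
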