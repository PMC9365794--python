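"""Evoked action-potential detection, counting, and shape measurement.

Excitability is quantified as the total number of evoked APs over the first
``count_steps`` (default 17) sweeps of the 3 pA step family.  Spike shape is
measured on the first evoked AP (the lowest-current sweep with a spike):
threshold is the first maximum of the second derivative of V(t) before the
peak, amplitude is peak − threshold, width is the full width at half maximum,
and the fast AHP is V(5 ms after the downstroke re-crosses threshold) minus
threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .config import AnalysisConfig, QCConfig, SpikeConfig
from .traces import AnalysisError, Recording, Trace

__all__ = ["SpikeShape", "QCResult", "detect_spikes", "count_total_evoked",
           "measure_spike_shape", "first_spiking_sweep", "qc_holding"]

log = logging.getLogger(__name__)


@dataclass
class SpikeShape:
    threshold: float          # mV
    amplitude: float          # mV, peak − threshold, > 0
    width_fwhm: float         # ms
    fast_ahp: float | None    # mV, V(recross + 5 ms) − threshold; None if
                              # the sweep ends first
    peak_time: float = np.nan

    def __post_init__(self) -> None:
        if not self.amplitude > 0:
            raise ValueError("spike amplitude must be positive")
        if not self.width_fwhm > 0:
            raise ValueError("FWHM must be positive")


@dataclass
class QCResult:
    holding_current: float | None   # pA; None if unavailable
    passed: bool | None             # None = indeterminate
    reasons: list[str]


def _odd_window(width_ms: float, dt: float, minimum: int = 5) -> int:
    w = max(int(round(width_ms / dt)), minimum)
    return w + 1 if w % 2 == 0 else w


def _smooth(v: np.ndarray, dt: float, window_ms: float) -> np.ndarray:
    w = _odd_window(window_ms, dt)
    if w >= v.size:
        return v
    return savgol_filter(v, w, polyorder=3)


def detect_spikes(trace: Trace, window_ms: tuple[float, float] | None = None,
                  config: SpikeConfig | None = None) -> list[float]:
    """Detect action-potential peak times (ms) in a current-clamp sweep.

    A detection requires a dV/dt upstroke crossing ``dvdt_thresh`` within a
    few ms before a voltage peak exceeding ``min_peak_mv``; peaks closer than
    ``refractory_ms`` merge into one (earliest kept).  The derivative is
    taken on a Savitzky–Golay-smoothed copy so that acquisition noise does
    not dominate it; peak times are refined on the raw trace.
    """
    if trace.kind != "voltage":
        raise TypeError("spike detection requires a voltage trace")
    cfg = config or SpikeConfig()
    v = trace.samples
    dt = trace.dt
    vs = _smooth(v, dt, max(cfg.sg_window_ms, 0.3))
    dvdt = np.gradient(vs, dt)

    above = vs >= cfg.min_peak_mv
    if not above.any():
        return []
    # candidate peaks: local maxima of the smoothed trace above min_peak_mv
    from scipy.signal import find_peaks
    distance = max(int(round(cfg.refractory_ms / dt)), 1)
    peaks, _ = find_peaks(vs, height=cfg.min_peak_mv, distance=distance)
    if peaks.size == 0:
        return []
    # require an upstroke crossing shortly before each peak
    look = int(round(5.0 / dt))
    out = []
    for p in peaks:
        pre = dvdt[max(p - look, 0):p + 1]
        if pre.size and pre.max() >= cfg.dvdt_thresh:
            lo = max(p - distance // 2, 0)
            hi = min(p + distance // 2 + 1, v.size)
            p_raw = lo + int(np.argmax(v[lo:hi]))
            out.append(trace.t0 + p_raw * dt)
    # refractory merge on refined times (keep the earliest of a cluster)
    merged: list[float] = []
    for t_pk in sorted(out):
        if merged and t_pk - merged[-1] < cfg.refractory_ms:
            log.debug("merged spike at %.3f ms into %.3f ms", t_pk, merged[-1])
            continue
        merged.append(t_pk)
    if window_ms is not None:
        t0, t1 = window_ms
        merged = [t for t in merged if t0 <= t < t1]
    return merged


def count_total_evoked(recording: Recording, count_steps: int | None = None,
                       config: SpikeConfig | None = None) -> int:
    """Total APs over the first ``count_steps`` sweeps (default from protocol).

    Spikes are counted inside the step epoch only; rebound spikes in the
    post-step baseline are excluded.
    """
    if recording.mode != "current_clamp":
        raise TypeError("evoked-AP counting requires a current-clamp recording")
    proto = recording.protocol
    if proto is None:
        raise AnalysisError("evoked-AP counting requires a step protocol")
    k = count_steps if count_steps is not None else proto.count_steps
    if recording.n_sweeps < k:
        raise AnalysisError(
            f"recording has {recording.n_sweeps} sweeps, fewer than count_steps={k}")
    total = 0
    for _, resp in recording.sweeps[:k]:
        total += len(detect_spikes(resp, proto.step_window, config))
    return total


def first_spiking_sweep(recording: Recording,
                        config: SpikeConfig | None = None) -> int:
    """Index of the lowest-current sweep containing ≥ 1 spike."""
    proto = recording.protocol
    window = proto.step_window if proto else None
    for i, (_, resp) in enumerate(recording.sweeps):
        if detect_spikes(resp, window, config):
            return i
    raise AnalysisError("no sweep contains a spike")


def _interp_crossing(t: np.ndarray, v: np.ndarray, level: float,
                     rising: bool) -> float:
    """Time of the first crossing of ``level`` (linear interpolation)."""
    if rising:
        idx = np.nonzero((v[:-1] < level) & (v[1:] >= level))[0]
    else:
        idx = np.nonzero((v[:-1] >= level) & (v[1:] < level))[0]
    if idx.size == 0:
        raise AnalysisError("no level crossing found")
    i = idx[0]
    frac = (level - v[i]) / (v[i + 1] - v[i])
    return t[i] + frac * (t[i + 1] - t[i])


def measure_spike_shape(trace: Trace, config: SpikeConfig | None = None,
                        window_ms: tuple[float, float] | None = None,
                        ) -> SpikeShape:
    """Measure threshold, amplitude, FWHM and fast AHP of the first spike.

    Threshold: the trace is Savitzky–Golay smoothed (window ``sg_window_ms``,
    order 3) and twice differentiated; the first local maximum of d²V/dt²
    exceeding ``d2v_rel_floor`` of the pre-peak global maximum, searched in
    the ``threshold_search_ms`` before the peak, marks threshold (earliest
    wins on ties).  The threshold *voltage* is read from the raw trace at
    that time.  Half-maximum crossings are linearly interpolated, giving a
    sub-sample FWHM.
    """
    cfg = config or SpikeConfig()
    peaks = detect_spikes(trace, window_ms, cfg)
    if not peaks:
        raise AnalysisError("no spike in sweep")
    t_peak = peaks[0]
    v = trace.samples
    dt = trace.dt
    t = trace.time
    i_peak = trace.index_at(t_peak)
    # refine to the raw local max
    r = int(round(cfg.refractory_ms / dt))
    lo = max(i_peak - r, 0)
    i_peak = lo + int(np.argmax(v[lo:min(i_peak + r, v.size)]))
    t_peak = t[i_peak]

    w = _odd_window(cfg.sg_window_ms, dt)
    d2v = savgol_filter(v, w, polyorder=3, deriv=2, delta=dt) \
        if w < v.size else np.gradient(np.gradient(v, dt), dt)
    i0 = max(i_peak - int(round(cfg.threshold_search_ms / dt)), 1)
    seg = d2v[i0:i_peak]
    if seg.size < 3:
        raise AnalysisError("peak too close to sweep start for threshold search")
    # "first maximum" = first local maximum that is prominent above BOTH a
    # fraction of the window maximum and the noise level of d²V itself
    # (MAD-based); prominence rather than height, so smoothing ripple riding
    # on the pre-threshold depolarizing ramp is ignored.  Earliest wins.
    from scipy.signal import find_peaks
    mad_sd = 1.4826 * float(np.median(np.abs(seg - np.median(seg))))
    floor = max(cfg.d2v_rel_floor * seg.max(), cfg.d2v_noise_k * mad_sd)
    cand, _ = find_peaks(seg, prominence=floor, height=floor)
    i_thr = i0 + (int(cand[0]) if cand.size else int(np.argmax(seg)))
    t_thr = t[i_thr]
    # refinement: the raw second difference peaks at the upstroke corner
    # itself (smoothing kernels smear it asymmetrically), but is only
    # trustworthy when the corner stands clear of the per-sample noise
    r = w // 2
    lo = max(i_thr - r, 1)
    hi = min(i_thr + r + 1, v.size - 1)
    d2_all = v[i0 - 1:i_peak - 1] - 2 * v[i0:i_peak] + v[i0 + 1:i_peak + 1]
    raw_sd = 1.4826 * float(np.median(np.abs(d2_all - np.median(d2_all))))
    d2_raw = v[lo - 1:hi - 1] - 2 * v[lo:hi] + v[lo + 1:hi + 1]
    if d2_raw.max() >= 6.0 * raw_sd:
        i_thr = lo + int(np.argmax(d2_raw))
        t_thr = t[i_thr]
    elif i0 < i_thr < i_peak - 1:
        # sub-sample peak of the smoothed d²V by parabolic interpolation
        y0, y1, y2 = d2v[i_thr - 1:i_thr + 2]
        denom = y0 - 2 * y1 + y2
        if denom != 0 and abs(0.5 * (y0 - y2) / denom) <= 1.0:
            t_thr = t[i_thr] + 0.5 * (y0 - y2) / denom * dt
    threshold = float(np.interp(t_thr, t, v))
    i_thr = trace.index_at(t_thr)
    amplitude = float(v[i_peak] - threshold)
    if amplitude <= 0:
        raise AnalysisError("non-positive spike amplitude")

    half = threshold + amplitude / 2.0
    t_up = _interp_crossing(t[i_thr:i_peak + 1], v[i_thr:i_peak + 1], half,
                            rising=True)
    # falling half crossing and threshold re-crossing after the peak
    after_t, after_v = t[i_peak:], v[i_peak:]
    t_down = _interp_crossing(after_t, after_v, half, rising=False)
    width = float(t_down - t_up)

    fast_ahp: float | None
    try:
        t_recross = _interp_crossing(after_t, after_v, threshold, rising=False)
        t_meas = t_recross + 5.0
        if t_meas > t[-1]:
            fast_ahp = None
        else:
            fast_ahp = float(np.interp(t_meas, t, v) - threshold)
    except AnalysisError:
        fast_ahp = None
    return SpikeShape(threshold=threshold, amplitude=amplitude,
                      width_fwhm=width, fast_ahp=fast_ahp, peak_time=t_peak)


def measure_first_spike_shape(recording: Recording,
                              config: SpikeConfig | None = None) -> SpikeShape:
    """Shape of the first evoked AP (lowest-current spiking sweep)."""
    i = first_spiking_sweep(recording, config)
    proto = recording.protocol
    window = proto.step_window if proto else None
    return measure_spike_shape(recording.sweeps[i][1], config, window)


def qc_holding(recording: Recording, config: QCConfig | None = None) -> QCResult:
    """Holding-current quality control.

    A neuron needing more than ``max_holding_pa`` (default 50 pA, strict
    inequality: exactly 50 pA passes) to sit at −60 mV is discarded from
    group statistics.  Holding current comes from metadata or, failing that,
    from the pre-step baseline of the command channel in current clamp.
    """
    cfg = config or QCConfig()
    holding = recording.metadata.get("holding_pa")
    if holding is None and recording.mode == "current_clamp" \
            and recording.protocol is not None:
        cmd = recording.sweeps[0][0]
        if cmd.kind == "current":
            i1 = cmd.index_at(recording.protocol.baseline_pre_ms)
            if i1 > 0:
                holding = float(np.mean(cmd.samples[:i1]))
    if holding is None:
        return QCResult(holding_current=None, passed=None,
                        reasons=["holding current unavailable"])
    if abs(holding) > cfg.max_holding_pa:
        return QCResult(holding_current=float(holding), passed=False,
                        reasons=[f"|holding| = {abs(holding):.1f} pA "
                                 f"> {cfg.max_holding_pa:.0f} pA"])
    return QCResult(holding_current=float(holding), passed=True, reasons=[])
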