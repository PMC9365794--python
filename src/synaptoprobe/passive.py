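"""Passive membrane properties: input conductance and capacitance.

Input conductance is the slope conductance between −70 and −50 mV holding:
(I(−50) − I(−70)) / 20 mV, in nS.  Capacitance comes from the membrane-test
transient, primarily by charge integration C = Q/ΔV (robust to
series-resistance distortion of the time constant), cross-checked against a
mono-exponential fit C = τ/R_m.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .config import PassiveConfig
from .traces import AnalysisError, Recording

__all__ = ["PassiveProps", "input_conductance", "estimate_capacitance"]


@dataclass
class PassiveProps:
    input_conductance: float | None    # nS
    capacitance: float | None          # pF (charge-integration estimate)
    capacitance_expfit: float | None = None   # pF (τ/R cross-check)
    fit_discrepancy: float | None = None      # |Q-est − fit-est| / Q-est
    notes: str = ""


def input_conductance(i_at_minus70: float, i_at_minus50: float) -> float:
    """ΔI/ΔV over the 20 mV between −70 and −50 mV holding, in nS.

    Both inputs are steady-state mean currents in pA; pA/mV = nS.
    """
    if not (np.isfinite(i_at_minus70) and np.isfinite(i_at_minus50)):
        raise ValueError("currents must be finite")
    return (i_at_minus50 - i_at_minus70) / 20.0


def _step_onset_index(cmd: np.ndarray, dt: float) -> int:
    dv = np.abs(np.diff(cmd))
    jumps = np.nonzero(dv > 0.5 * dv.max())[0] if dv.max() > 0 else np.array([])
    if jumps.size == 0:
        raise AnalysisError("membrane test has no voltage step")
    return int(jumps[0]) + 1


def estimate_capacitance(membrane_test: Recording,
                         config: PassiveConfig | None = None) -> PassiveProps:
    """Estimate whole-cell capacitance from a membrane-test recording.

    Sweeps are averaged; the command channel locates the step and gives ΔV.
    The charge Q of the transient above the post-step Ohmic plateau
    (steady-state window = final ``baseline_frac`` of the step epoch) gives
    C = Q/ΔV; a mono-exponential fit of the transient gives τ and, with
    R_m = ΔV/I_plateau, the cross-check C = τ/R_m.  Both estimates and their
    relative discrepancy are reported.
    """
    cfg = config or PassiveConfig()
    dt = membrane_test.dt
    cmd = np.mean([c.samples for c, _ in membrane_test.sweeps], axis=0)
    cur = np.mean([r.samples for _, r in membrane_test.sweeps], axis=0)

    i_on = _step_onset_index(cmd, dt)
    if i_on < 2 or cur.size - i_on < 10:
        raise AnalysisError("step too close to the sweep edge")
    base_v = float(np.mean(cmd[:i_on]))
    base_i = float(np.mean(cur[:max(i_on - 2, 1)]))
    n_post = cur.size - i_on
    plateau_lo = i_on + int((1.0 - cfg.baseline_frac) * n_post)
    delta_v = float(np.mean(cmd[plateau_lo:]) - base_v)
    if delta_v == 0 or abs(delta_v) < 1e-9:
        raise AnalysisError("no voltage step (ΔV = 0); cannot estimate C")
    plateau_i = float(np.mean(cur[plateau_lo:])) - base_i

    transient = cur[i_on:plateau_lo] - base_i - plateau_i
    # require a resolvable transient: must not decay away within 2 samples
    peak = transient[np.argmax(np.abs(transient))]
    if abs(peak) < 5e-3 * abs(plateau_i) or transient.size < 3:
        raise AnalysisError("no resolvable charging transient")
    q_fc = float(np.sum(transient) * dt)           # pA·ms = fC
    c_q = q_fc / delta_v                           # fC/mV = pF

    # mono-exponential cross-check on the transient
    c_fit = None
    try:
        t_fit = np.arange(transient.size) * dt
        n_fit = min(transient.size, int(cfg.fit_window_ms / dt))
        sign = np.sign(peak) or 1.0
        y = sign * transient[:n_fit]
        tt = t_fit[:n_fit]
        a0 = max(y[0], 1e-6)
        tau0 = max(q_fc / (sign * a0), dt)
        popt, _ = curve_fit(lambda x, a, tau: a * np.exp(-x / tau), tt, y,
                            p0=[a0, tau0], bounds=([0, dt * 0.5], [np.inf, np.inf]),
                            maxfev=2000)
        tau_ms = popt[1]
        r_gohm = delta_v / plateau_i               # mV/pA = GΩ
        c_fit = float(tau_ms / r_gohm)             # ms/GΩ = pF
    except (RuntimeError, ValueError, ZeroDivisionError):
        pass

    disc = abs(c_q - c_fit) / abs(c_q) if c_fit is not None else None
    return PassiveProps(input_conductance=None, capacitance=float(c_q),
                        capacitance_expfit=c_fit, fit_discrepancy=disc,
                        notes=f"charge integration over {transient.size} samples, "
                              f"dV={delta_v:.3g} mV")
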