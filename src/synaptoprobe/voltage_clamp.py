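"""Sodium and potassium current families from voltage-step recordings.

Per step, after subtracting the pre-step baseline: the sodium peak is the
most negative current in an early window just after step onset (first
0.5 ms blanked against the capacitive artifact), the fast potassium current
is the maximum in that same early window, and the slow potassium current is
the mean over the final 50 ms of the 400 ms step.  All three are normalized
by the cell capacitance to densities in pA/pF.  When the inward transient
overlaps the potassium rise the "fast K" value is the net outward peak —
this is the operational definition, not an ionic decomposition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .config import VCConfig
from .traces import AnalysisError, Recording

__all__ = ["IVCurves", "extract_iv_curves", "density_at_voltage"]

log = logging.getLogger(__name__)


@dataclass
class IVCurves:
    step_voltages: np.ndarray       # mV
    na_peak_density: np.ndarray     # pA/pF, entries ≤ 0
    kfast_density: np.ndarray       # pA/pF
    kslow_density: np.ndarray       # pA/pF
    capacitance_used: float         # pF; NaN when unnormalized
    unnormalized: bool = False      # True → values are raw pA

    def __post_init__(self) -> None:
        n = self.step_voltages.size
        for name in ("na_peak_density", "kfast_density", "kslow_density"):
            arr = getattr(self, name)
            if arr.size != n:
                raise ValueError(f"{name} length differs from step_voltages")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite values")
        if np.any(self.na_peak_density > 0):
            raise ValueError("na_peak_density must be ≤ 0")


def _step_voltages_from_commands(recording: Recording) -> np.ndarray:
    proto = recording.protocol
    on, off = proto.step_window
    volts = []
    for cmd, _ in recording.sweeps:
        seg = cmd.slice(on + 1.0, off - 1.0)
        volts.append(float(np.median(seg.samples)))
    return np.asarray(volts)


def extract_iv_curves(recording: Recording, capacitance: float | None,
                      config: VCConfig | None = None) -> IVCurves:
    """Extract Na / fast-K / slow-K current densities from a step family.

    ``capacitance`` in pF; pass ``None`` to obtain raw pA values flagged
    ``unnormalized`` (never silently).  Step voltages are read from the
    command channel when it carries the steps, else from the protocol.
    """
    if recording.mode != "voltage_clamp":
        raise TypeError("I–V extraction requires a voltage-clamp recording")
    proto = recording.protocol
    if proto is None:
        raise AnalysisError("I–V extraction requires a step protocol")
    cfg = config or VCConfig()
    if capacitance is not None and not capacitance > 0:
        raise ValueError("capacitance must be positive")

    cmd0 = recording.sweeps[0][0]
    if cmd0.kind == "voltage" and np.ptp(cmd0.samples) > 0.5 or \
            any(np.ptp(c.samples) > 0.5 for c, _ in recording.sweeps):
        volts = _step_voltages_from_commands(recording)
    else:
        volts = proto.step_levels()

    on, off = proto.step_window
    dt = recording.dt
    c = capacitance if capacitance is not None else 1.0
    na, kf, ks = [], [], []
    for _, resp in recording.sweeps:
        i_on = resp.index_at(on)
        if i_on < 2:
            raise AnalysisError("no resolvable pre-step baseline")
        baseline = float(np.mean(resp.samples[:i_on]))
        early = resp.slice(on + cfg.blank_ms, on + cfg.early_ms).samples - baseline
        late = resp.slice(off - cfg.late_ms, off).samples - baseline
        na.append(min(float(early.min()), 0.0) / c)
        kf.append(float(early.max()) / c)
        ks.append(float(late.mean()) / c)
    return IVCurves(step_voltages=volts, na_peak_density=np.asarray(na),
                    kfast_density=np.asarray(kf), kslow_density=np.asarray(ks),
                    capacitance_used=float(c) if capacitance is not None else np.nan,
                    unnormalized=capacitance is None)


def density_at_voltage(iv: IVCurves, v: float,
                       component: str) -> float:
    """Density (pA/pF) at step voltage ``v`` — nearest-grid lookup.

    No interpolation: the nearest step is returned provided it lies within
    half the grid spacing of the query; otherwise the query is out of range.
    """
    arrays = {"na": iv.na_peak_density, "kfast": iv.kfast_density,
              "kslow": iv.kslow_density}
    if component not in arrays:
        raise ValueError(f"unknown component {component!r}")
    volts = iv.step_voltages
    spacing = float(np.min(np.abs(np.diff(volts)))) if volts.size > 1 else np.inf
    i = int(np.argmin(np.abs(volts - v)))
    if abs(volts[i] - v) > spacing / 2.0 + 1e-9:
        raise ValueError(f"voltage {v} mV outside the step grid")
    if abs(volts[i] - v) > 1e-9:
        log.info("density_at_voltage: %.1f mV mapped to grid step %.1f mV",
                 v, volts[i])
    return float(arrays[component][i])
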