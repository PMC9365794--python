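"""Per-neuron feature extraction: one neuron's recordings → NeuronFeatures.

Runs QC, evoked-AP counting, first-spike shape, capacitance, input
conductance, capacitance-normalized I–V densities, and EPSC detection with
per-event decay fits, each stage tolerant of a missing recording (the
corresponding features stay missing, never 0).
"""

from __future__ import annotations

import logging

import numpy as np

from .config import AnalysisConfig
from .events import detect_epscs, summarize_events
from .passive import PassiveProps, estimate_capacitance, input_conductance
from .spikes import count_total_evoked, measure_first_spike_shape, qc_holding
from .stats import NeuronFeatures
from .traces import AnalysisError, Recording
from .voltage_clamp import extract_iv_curves

__all__ = ["extract_neuron_features", "input_conductance_from_iv"]

log = logging.getLogger(__name__)


def input_conductance_from_iv(recording: Recording,
                              config: AnalysisConfig | None = None) -> float | None:
    """Input conductance from the −70 and −50 mV steps of a VC family.

    Steady-state currents (final ``passive.baseline_frac`` of the step) at
    the steps commanding −70 and −50 mV give ΔI/20 mV in nS.  Returns None
    if the family does not contain both voltages.
    """
    cfg = config or AnalysisConfig()
    proto = recording.protocol
    if proto is None:
        return None
    volts = proto.step_levels()
    currents = {}
    on, off = proto.step_window
    tail = proto.step_duration * cfg.passive.baseline_frac
    for v, (_, resp) in zip(volts, recording.sweeps):
        for target in (-70.0, -50.0):
            if abs(v - target) < 1e-6:
                seg = resp.slice(off - tail, off)
                currents[target] = float(np.mean(seg.samples))
    if len(currents) < 2:
        return None
    return input_conductance(currents[-70.0], currents[-50.0])


def extract_neuron_features(cell_id: str, group_label: str,
                            epsc: Recording | None = None,
                            current_clamp: Recording | None = None,
                            voltage_clamp: Recording | None = None,
                            membrane_test: Recording | None = None,
                            config: AnalysisConfig | None = None,
                            ) -> NeuronFeatures:
    cfg = config or AnalysisConfig()
    feats = NeuronFeatures(cell_id=cell_id, group_label=group_label)

    if current_clamp is not None:
        feats.qc = qc_holding(current_clamp, cfg.qc)
        try:
            feats.total_evoked_ap = count_total_evoked(
                current_clamp, cfg.protocol.count_steps
                if current_clamp.protocol is None else None, cfg.spike)
        except AnalysisError as exc:
            log.warning("%s: evoked-AP count failed: %s", cell_id, exc)
        try:
            feats.spike_shape = measure_first_spike_shape(current_clamp, cfg.spike)
        except AnalysisError:
            log.info("%s: no evoked spike; shape metrics missing", cell_id)

    passive = PassiveProps(input_conductance=None, capacitance=None)
    if membrane_test is not None:
        try:
            passive = estimate_capacitance(membrane_test, cfg.passive)
        except AnalysisError as exc:
            log.warning("%s: capacitance estimation failed: %s", cell_id, exc)
    if voltage_clamp is not None:
        passive.input_conductance = input_conductance_from_iv(voltage_clamp, cfg)
    feats.passive = passive

    if voltage_clamp is not None:
        try:
            feats.iv = extract_iv_curves(voltage_clamp, passive.capacitance,
                                         cfg.vc)
        except (AnalysisError, ValueError) as exc:
            log.warning("%s: I–V extraction failed: %s", cell_id, exc)

    if epsc is not None:
        trace = epsc.sweeps[0][1]
        events = detect_epscs(trace, cfg.epsc)
        duration_s = epsc.metadata.get("duration_s", trace.duration / 1000.0)
        feats.epsc = summarize_events(events, float(duration_s))
    return feats
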