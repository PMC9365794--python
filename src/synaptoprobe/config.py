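"""Run configuration: documented defaults, strict schema validation.

Every constant the extraction stages use is a config key, so a run log can
state exactly which detector settings produced a given feature table.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["SpikeConfig", "QCConfig", "PassiveConfig", "VCConfig",
           "EPSCConfig", "AnalysisConfig", "ConfigError", "load_config"]


class ConfigError(ValueError):
    """Configuration file violates the schema."""


@dataclass
class SpikeConfig:
    """Action-potential detection and shape measurement."""

    dvdt_thresh: float = 10.0      # mV/ms; onset criterion for a spike
    min_peak_mv: float = -20.0     # absolute peak requirement
    refractory_ms: float = 2.0     # detections closer than this merge
    sg_window_ms: float = 0.5      # Savitzky–Golay window for derivatives
    threshold_search_ms: float = 10.0   # pre-peak window for threshold search
    d2v_rel_floor: float = 0.10    # "first maximum" must exceed this fraction
                                   # of the pre-peak global maximum
    d2v_noise_k: float = 4.0       # ... and this multiple of the robust
                                   # noise SD of the second derivative


@dataclass
class QCConfig:
    max_holding_pa: float = 50.0   # strict: |holding| > 50 pA fails
    exclude_indeterminate: bool = True


@dataclass
class PassiveConfig:
    baseline_frac: float = 0.25    # final fraction of each epoch = steady state
    fit_window_ms: float = 60.0    # span of the mono-exponential check fit


@dataclass
class VCConfig:
    early_ms: float = 10.0         # early window end, after step onset
    blank_ms: float = 0.5          # capacitive-artifact blank at step onset
    late_ms: float = 50.0          # late window = final late_ms of the step


@dataclass
class EPSCConfig:
    min_amp_pa: float = 5.0        # absolute detector floor
    noise_k: float = 4.0           # threshold = max(floor, k * robust SD)
    baseline_ms: float = 200.0     # median baseline-tracker window
    lowpass_hz: float = 1000.0     # Bessel-type low-pass corner
    tau_window_ms: float = 20.0    # decay-fit window after the peak
    match_ms: float = 2.0          # ground-truth matching tolerance (oracles)
    min_r2: float = 0.5            # decay fits below this R² are discarded
    min_duration_warn_s: float = 10.0


@dataclass
class ProtocolConfig:
    """Step-protocol defaults used when a file carries no command channel."""

    n_steps: int = 35
    count_steps: int = 17
    start_offset_pa: float = -12.0
    increment_pa: float = 3.0
    step_duration_ms: float = 400.0

    def __post_init__(self) -> None:
        if not (1 <= self.count_steps <= self.n_steps):
            raise ConfigError(
                f"count_steps={self.count_steps} must lie in [1, n_steps={self.n_steps}]")


@dataclass
class AnalysisConfig:
    spike: SpikeConfig = field(default_factory=SpikeConfig)
    qc: QCConfig = field(default_factory=QCConfig)
    passive: PassiveConfig = field(default_factory=PassiveConfig)
    vc: VCConfig = field(default_factory=VCConfig)
    epsc: EPSCConfig = field(default_factory=EPSCConfig)
    protocol: ProtocolConfig = field(default_factory=ProtocolConfig)
    apply_junction_correction: bool = False   # −10 mV reporting shift, off by
                                              # default (figures use commanded V)
    pool_groups: dict = field(default_factory=dict)  # e.g. {"Parkin": ["Parkin1", "Parkin2"]}

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


_SECTIONS = {"spike": SpikeConfig, "qc": QCConfig, "passive": PassiveConfig,
             "vc": VCConfig, "epsc": EPSCConfig, "protocol": ProtocolConfig}
_SCALARS = {"apply_junction_correction", "pool_groups"}


def _build_section(cls, data: dict, section: str):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - valid
    if unknown:
        raise ConfigError(
            f"unknown key(s) in [{section}]: {', '.join(sorted(unknown))}")
    return cls(**data)


def config_from_dict(data: dict | None) -> AnalysisConfig:
    """Build a validated :class:`AnalysisConfig`; unknown keys are rejected."""
    data = dict(data or {})
    unknown = set(data) - set(_SECTIONS) - _SCALARS
    if unknown:
        raise ConfigError(f"unknown top-level key(s): {', '.join(sorted(unknown))}")
    kwargs = {}
    for name, cls in _SECTIONS.items():
        section = data.get(name, {})
        if not isinstance(section, dict):
            raise ConfigError(f"[{name}] must be a mapping")
        kwargs[name] = _build_section(cls, section, name)
    for name in _SCALARS:
        if name in data:
            kwargs[name] = data[name]
    return AnalysisConfig(**kwargs)


def load_config(path: str | Path) -> AnalysisConfig:
    """Load a YAML (or JSON, a YAML subset) config file.

    An empty file yields all documented defaults.
    """
    text = Path(path).read_text()
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    return config_from_dict(data)
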