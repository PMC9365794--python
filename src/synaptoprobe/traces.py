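"""Core in-memory containers for patch-clamp data.

Unit conventions used throughout the package: voltage in mV, current in pA,
time in ms (sampling interval ``dt`` is ms per sample), conductance in nS,
capacitance in pF.  With these units nS = pA/mV and pF = fC/mV, so the usual
electrophysiology formulas need no conversion factors.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

__all__ = ["Trace", "StepProtocol", "Recording", "AnalysisError"]


class AnalysisError(RuntimeError):
    """A recording could not be analyzed (missing spike, bad window, ...)."""


ChannelKind = Literal["voltage", "current"]


@dataclass
class Trace:
    """One sampled channel.

    Parameters
    ----------
    samples : array of float
        mV for voltage channels, pA for current channels.
    dt : float
        Sampling interval in ms.
    kind : {"voltage", "current"}
    t0 : float
        Time of the first sample, ms (sweep-relative).
    """

    samples: np.ndarray
    dt: float
    kind: ChannelKind
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("trace must be a non-empty 1-D array")
        if not self.dt > 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if self.kind not in ("voltage", "current"):
            raise ValueError(f"unknown channel kind {self.kind!r}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("trace contains non-finite samples")

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Total span in ms."""
        return self.n * self.dt

    @property
    def time(self) -> np.ndarray:
        """Sample times in ms."""
        return self.t0 + np.arange(self.n) * self.dt

    def index_at(self, t_ms: float) -> int:
        """Index of the sample nearest to ``t_ms`` (clipped to range)."""
        i = int(round((t_ms - self.t0) / self.dt))
        return min(max(i, 0), self.n - 1)

    def slice(self, t_start: float, t_stop: float) -> "Trace":
        """Sub-trace covering [t_start, t_stop) in ms."""
        i0 = self.index_at(t_start)
        i1 = max(self.index_at(t_stop), i0 + 1)
        return Trace(self.samples[i0:i1], self.dt, self.kind,
                     t0=self.t0 + i0 * self.dt)


@dataclass
class StepProtocol:
    """Family of square steps from a holding level.

    ``holding_level`` and the step offsets are pA in current clamp and mV in
    voltage clamp.  The command of step *i* (0-based) is
    ``holding_level + start_offset + i * increment`` during the step epoch,
    which begins ``baseline_pre_ms`` into each sweep and lasts
    ``step_duration``.  ``count_steps`` is the number of initial steps used
    when counting evoked action potentials.
    """

    mode: Literal["current_clamp", "voltage_clamp"]
    holding_level: float
    start_offset: float
    increment: float
    step_duration: float = 400.0
    n_steps: int = 35
    baseline_pre_ms: float = 100.0
    baseline_post_ms: float = 100.0
    count_steps: int = 17

    def __post_init__(self) -> None:
        if self.increment == 0:
            raise ValueError("increment must be non-zero")
        if not self.step_duration > 0:
            raise ValueError("step_duration must be positive")
        if not (1 <= self.count_steps <= self.n_steps):
            raise ValueError(
                f"count_steps={self.count_steps} must lie in [1, n_steps={self.n_steps}]")

    @classmethod
    def current_clamp_default(cls) -> "StepProtocol":
        """35 depolarization steps of 3 pA starting 12 pA below holding."""
        return cls(mode="current_clamp", holding_level=0.0, start_offset=-12.0,
                   increment=3.0, step_duration=400.0, n_steps=35,
                   count_steps=17)

    @classmethod
    def voltage_clamp_default(cls) -> "StepProtocol":
        """400 ms voltage steps, −90 to +80 mV in 10 mV, from −60 mV hold."""
        return cls(mode="voltage_clamp", holding_level=-60.0,
                   start_offset=-30.0, increment=10.0, step_duration=400.0,
                   n_steps=18, count_steps=1)

    def step_levels(self) -> np.ndarray:
        """Absolute command level of every step."""
        return (self.holding_level + self.start_offset
                + self.increment * np.arange(self.n_steps))

    def relative_levels(self) -> np.ndarray:
        """Command level of every step relative to holding."""
        return self.start_offset + self.increment * np.arange(self.n_steps)

    @property
    def step_window(self) -> tuple[float, float]:
        """(onset, offset) of the step epoch in sweep-relative ms."""
        return self.baseline_pre_ms, self.baseline_pre_ms + self.step_duration

    @property
    def sweep_duration(self) -> float:
        return self.baseline_pre_ms + self.step_duration + self.baseline_post_ms


@dataclass
class Recording:
    """A set of sweeps from one cell under one protocol.

    ``sweeps`` holds (command, response) trace pairs.  Gap-free recordings
    (spontaneous EPSCs, membrane tests without a step family) have
    ``protocol is None`` and typically a single sweep.
    """

    cell_id: str
    group_label: str
    mode: Literal["current_clamp", "voltage_clamp"]
    sweeps: list[tuple[Trace, Trace]]
    protocol: StepProtocol | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sweeps:
            raise ValueError("recording must contain at least one sweep")
        dt0 = self.sweeps[0][1].dt
        for cmd, resp in self.sweeps:
            if abs(cmd.dt - dt0) > 1e-12 or abs(resp.dt - dt0) > 1e-12:
                raise ValueError("all sweeps must share one sampling interval")
            if cmd.n != resp.n:
                raise ValueError("command/response lengths differ within a sweep")

    @property
    def dt(self) -> float:
        return self.sweeps[0][1].dt

    @property
    def n_sweeps(self) -> int:
        return len(self.sweeps)

    @property
    def gap_free(self) -> bool:
        return self.protocol is None

    def with_metadata(self, **kv) -> "Recording":
        md = dict(self.metadata)
        md.update(kv)
        return replace(self, metadata=md)
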