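"""Scoring detected events against a known inventory.

Used to validate the EPSC detector against the synthetic generator's
ground truth: greedy one-to-one matching of detected peaks to true event
times within a tolerance window, yielding recall / precision / rate bias.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["MatchResult", "match_events", "detection_metrics"]


@dataclass
class MatchResult:
    n_true: int
    n_detected: int
    true_positives: int

    @property
    def recall(self) -> float:
        return self.true_positives / self.n_true if self.n_true else 1.0

    @property
    def precision(self) -> float:
        return self.true_positives / self.n_detected if self.n_detected else 1.0

    def __add__(self, other: "MatchResult") -> "MatchResult":
        return MatchResult(self.n_true + other.n_true,
                           self.n_detected + other.n_detected,
                           self.true_positives + other.true_positives)


def match_events(true_times: np.ndarray, detected_times: np.ndarray,
                 tol_ms: float = 2.0) -> MatchResult:
    """Greedy nearest-neighbour one-to-one matching within ``tol_ms``.

    True events are visited in order; each claims the nearest unclaimed
    detection within the tolerance.  One detection can satisfy only one
    true event, so a merged double-event counts one hit and one miss.
    """
    true_times = np.asarray(true_times, float)
    det = np.asarray(detected_times, float)
    used = np.zeros(det.size, dtype=bool)
    tp = 0
    for t in true_times:
        if det.size == 0:
            break
        d = np.abs(det - t)
        d[used] = np.inf
        j = int(np.argmin(d))
        if d[j] <= tol_ms:
            used[j] = True
            tp += 1
    return MatchResult(n_true=true_times.size, n_detected=det.size,
                       true_positives=tp)


def detection_metrics(results: list[MatchResult]) -> dict:
    """Pool per-recording match results into overall recall/precision/bias."""
    total = MatchResult(0, 0, 0)
    for r in results:
        total = total + r
    bias = (total.n_detected - total.n_true) / total.n_true if total.n_true else 0.0
    return {"recall": total.recall, "precision": total.precision,
            "rate_bias": bias, "n_true": total.n_true,
            "n_detected": total.n_detected}
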