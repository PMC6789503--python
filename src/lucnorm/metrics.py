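"""Evaluation statistics comparing estimated activities to a known truth.

Used by the simulation benchmark: over M repeated simulated experiments with
true activity A and per-repeat estimates A_k, three summaries are computed.

* ``relative_bias`` — |A − A_k| / A per estimate; the benchmark reports its
  90th percentile (P90) across repeats as an accuracy measure.
* ``relative_mad`` — median absolute deviation of the A_k divided by A, a
  precision measure (no normal-consistency factor is applied).
* ``zamar_criterion`` — a rotation-invariant discrepancy between estimated
  and true slopes, mean over k of
  1 − |1 + A_k·A| / ((1+A_k²)^{1/2} (1+A²)^{1/2}),
  which is 0 when every estimate equals the truth and 1 at the
  perpendicular slope −1/A.  Because it depends only on the angle between
  the lines, it compares methods fairly across activity levels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "relative_bias",
    "zamar_criterion",
    "relative_mad",
    "percentile",
    "EvaluationSummary",
]


def relative_bias(true_activity: float, estimate: float) -> float:
    """Relative absolute estimation error |A − A_k| / A."""
    if true_activity == 0:
        raise ValueError("relative bias is undefined for true activity 0")
    return abs(true_activity - estimate) / true_activity


def zamar_criterion(true_activity: float, estimates) -> float:
    """Rotation-invariant slope discrepancy in [0, 1]; 0 means perfect recovery."""
    a = float(true_activity)
    ak = np.asarray(estimates, dtype=float)
    if ak.size == 0:
        raise ValueError("at least one estimate is required")
    # sqrt of the product (not product of sqrts) so perfect estimates give
    # a term of exactly 0 and the perpendicular slope -1/A exactly 1
    terms = 1.0 - np.abs(1.0 + ak * a) / np.sqrt((1.0 + ak * ak) * (1.0 + a * a))
    return float(np.mean(terms))


def relative_mad(true_activity: float, estimates) -> float:
    """Median absolute deviation of the estimates divided by the true activity."""
    if true_activity == 0:
        raise ValueError("relative MAD is undefined for true activity 0")
    ak = np.asarray(estimates, dtype=float)
    if ak.size == 0:
        raise ValueError("at least one estimate is required")
    return float(np.median(np.abs(ak - np.median(ak))) / true_activity)


def percentile(values, p: float) -> float:
    """p-th percentile with linear interpolation between order statistics."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("percentile of an empty vector is undefined")
    if not 0.0 <= p <= 100.0:
        raise ValueError("p must lie in [0, 100]")
    return float(np.percentile(v, p))


@dataclass(frozen=True)
class EvaluationSummary:
    """Per-method metrics over M simulation repeats."""

    method: str
    true_activity: float
    estimates: np.ndarray
    m: int = field(init=False)
    zamar: float = field(init=False)
    p90_relative_bias: float = field(init=False)
    relative_mad: float = field(init=False)

    def __post_init__(self) -> None:
        est = np.asarray(self.estimates, dtype=float)
        if est.size == 0:
            raise ValueError("at least one estimate is required")
        object.__setattr__(self, "estimates", est)
        object.__setattr__(self, "m", int(est.size))
        object.__setattr__(self, "zamar", zamar_criterion(self.true_activity, est))
        object.__setattr__(
            self,
            "p90_relative_bias",
            percentile([relative_bias(self.true_activity, a) for a in est], 90.0),
        )
        object.__setattr__(self, "relative_mad", relative_mad(self.true_activity, est))
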