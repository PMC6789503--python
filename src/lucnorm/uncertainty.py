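"""Bootstrap confidence intervals for activity estimates.

The basic (reverse-percentile) bootstrap is used: replicate pairs
(R_i, F_i) are resampled with replacement, the estimator is re-run on each
resample, and the interval is

    (2·Â − q_{1−α/2},  2·Â − q_{α/2})

with Â the full-data estimate and q the empirical quantiles of the
bootstrap slopes (linear interpolation between order statistics).  The
"basic_positive" variant additionally clamps the lower bound at 0, since
relative activities are physically non-negative.

Resamples on which the estimator fails (e.g. a ratio resample containing a
zero Renilla value) are dropped and counted; the interval is refused if
fewer than half the resamples succeed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Union

import numpy as np

from .estimators import ESTIMATORS, ActivityEstimate, EstimationError, ReplicateSet

__all__ = ["BootstrapSpec", "BootstrapError", "bootstrap_ci"]

_CI_METHODS = ("basic", "basic_positive")


class BootstrapError(RuntimeError):
    """Raised when too few bootstrap resamples produce a valid estimate."""


@dataclass(frozen=True)
class BootstrapSpec:
    """Bootstrap configuration: 999 replicates and a 95% interval by default."""

    n_boot: int = 999
    alpha: float = 0.05
    method: str = "basic"
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.method not in _CI_METHODS:
            raise ValueError(
                f"unknown interval method {self.method!r}; options: {', '.join(_CI_METHODS)}"
            )


def bootstrap_ci(
    data: ReplicateSet,
    estimator: Union[str, Callable[[ReplicateSet], ActivityEstimate]],
    spec: BootstrapSpec = BootstrapSpec(),
) -> tuple[float, float]:
    """Basic bootstrap confidence interval for an activity estimator.

    Parameters
    ----------
    data : ReplicateSet
        Paired luminescence measurements (n >= 2).
    estimator : str or callable
        An identifier from :data:`lucnorm.estimators.ESTIMATORS`
        ("ratio", "ols", "eiv", "reiv") or any callable mapping a
        ReplicateSet to an ActivityEstimate.
    spec : BootstrapSpec
        Number of resamples, significance level, interval variant and seed.

    Returns
    -------
    (ci_lower, ci_upper) : tuple of float
    """
    if isinstance(estimator, str):
        try:
            fit = ESTIMATORS[estimator]
        except KeyError:
            raise ValueError(
                f"unknown estimator {estimator!r}; options: {', '.join(ESTIMATORS)}"
            ) from None
    else:
        fit = estimator
    if data.n < 2:
        raise ValueError("bootstrap requires at least 2 replicates")

    point = fit(data).activity  # must succeed on the full data
    rng = np.random.default_rng(spec.seed)
    slopes = []
    n_failed = 0
    for _ in range(spec.n_boot):
        idx = rng.integers(0, data.n, size=data.n)
        resample = ReplicateSet(renilla=data.renilla[idx], firefly=data.firefly[idx])
        try:
            slopes.append(fit(resample).activity)
        except EstimationError:
            n_failed += 1
    if len(slopes) < 0.5 * spec.n_boot:
        raise BootstrapError(
            f"only {len(slopes)} of {spec.n_boot} bootstrap resamples produced an "
            "estimate; the interval would be unreliable"
        )
    q_lo, q_hi = np.quantile(slopes, [spec.alpha / 2.0, 1.0 - spec.alpha / 2.0])
    lower = 2.0 * point - float(q_hi)
    upper = 2.0 * point - float(q_lo)
    if spec.method == "basic_positive":
        lower = max(lower, 0.0)
        upper = max(upper, lower)
    return lower, upper
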