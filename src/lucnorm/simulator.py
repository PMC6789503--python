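"""Synthetic dual-reporter luminescence data with known ground truth.

The generative model emulates a transient transfection experiment.  Each
replicate i receives a transfection efficiency t_i drawn from a Beta
distribution (its coefficient of variation rises as the mean efficiency
falls, mirroring hard-to-transfect cell lines).  Renilla luminescence is
proportional to t_i up to a maximal luminescence r_max, and firefly
luminescence additionally carries the true relative activity A::

    R_i = r_max * t_i + CN(sigma11^2, sigma12^2, gamma)
    F_i = A * r_max * t_i + CN(sigma21^2, sigma22^2, gamma)

where CN(s1^2, s2^2, gamma) is the contaminated normal mixture
(1-gamma)*N(0, s1^2) + gamma*N(0, s2^2): occasional gross errors
(outliers) occur with frequency gamma and standard deviation s2.  Renilla
and firefly errors are drawn independently of each other and of t_i.

Firefly error magnitudes scale with activity (sigma21 = A*sigma11,
sigma22 = A*sigma12) unless overridden, since the firefly signal itself is
A times larger.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, replace
from typing import Optional

import numpy as np

from .estimators import ReplicateSet

__all__ = [
    "TRANSFECTION_BETA_TABLE",
    "SimulationConfig",
    "SimulatedExperiment",
    "beta_params_for_mean",
    "sample_transfection",
    "contaminated_normal",
    "firefly_sigmas_from_activity",
    "simulate_experiment",
]

#: Beta(alpha, beta) parameter pairs for each supported mean transfection
#: efficiency t̄ = alpha/(alpha+beta).
TRANSFECTION_BETA_TABLE: dict[float, tuple[float, float]] = {
    0.1: (2.0, 18.0),
    0.25: (2.0, 6.0),
    0.5: (2.0, 2.0),
    0.75: (6.0, 2.0),
    0.9: (18.0, 2.0),
}


def beta_params_for_mean(tbar: float) -> tuple[float, float]:
    """Beta (alpha, beta) pair for a tabulated mean transfection efficiency."""
    try:
        alpha, beta = TRANSFECTION_BETA_TABLE[tbar]
    except KeyError:
        supported = ", ".join(str(k) for k in TRANSFECTION_BETA_TABLE)
        raise ValueError(
            f"mean transfection efficiency {tbar!r} is not tabulated; "
            f"supported values: {supported}"
        ) from None
    assert alpha / (alpha + beta) == tbar
    return alpha, beta


def sample_transfection(
    n: int, alpha: float, beta: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw n independent per-sample transfection efficiencies from Beta(alpha, beta)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if alpha <= 0 or beta <= 0:
        raise ValueError("Beta parameters must be positive")
    return rng.beta(alpha, beta, size=n)


def contaminated_normal(
    n: int,
    sigma1: float,
    sigma2: float,
    gamma: float,
    rng: np.random.Generator,
    return_labels: bool = False,
):
    """Draw n errors from (1-gamma)·N(0, sigma1²) + gamma·N(0, sigma2²).

    The mixture component is chosen independently per draw.  With
    ``return_labels=True`` also returns the boolean vector of draws that came
    from the contaminating (sigma2) component.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if sigma1 < 0 or sigma2 < 0:
        raise ValueError("standard deviations must be non-negative")
    if not 0.0 <= gamma <= 1.0:
        raise ValueError("contamination fraction gamma must lie in [0, 1]")
    contaminated = rng.random(n) < gamma
    sd = np.where(contaminated, sigma2, sigma1)
    draws = rng.standard_normal(n) * sd
    if return_labels:
        return draws, contaminated
    return draws


def firefly_sigmas_from_activity(
    activity: float, sigma11: float, sigma12: float
) -> tuple[float, float]:
    """Firefly error SDs scaled with activity: (A·sigma11, A·sigma12)."""
    if activity <= 0:
        raise ValueError("activity must be positive")
    return activity * sigma11, activity * sigma12


@dataclass(frozen=True)
class SimulationConfig:
    """All generative parameters of a simulated dual-reporter experiment.

    ``sigma21``/``sigma22`` default to None, meaning "scale the Renilla
    error SDs by the true activity".  ``r_max`` is the maximal Renilla
    luminescence in RLU; 20 RLU is the library default, matching the RLU
    scale on which a Renilla error SD of 3 represents substantial relative
    noise at low transfection efficiency.
    """

    true_activity: float = 10.0
    n: int = 10
    alpha: float = 2.0
    beta: float = 6.0
    r_max: float = 20.0
    sigma11: float = 3.0
    sigma12: float = 3.0
    sigma21: Optional[float] = None
    sigma22: Optional[float] = None
    gamma: float = 0.05
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("Beta parameters must be positive")
        if self.r_max <= 0:
            raise ValueError("r_max must be positive")
        for name in ("sigma11", "sigma12", "sigma21", "sigma22"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must lie in [0, 1]")

    @property
    def tbar(self) -> float:
        """Mean transfection efficiency alpha/(alpha+beta)."""
        return self.alpha / (self.alpha + self.beta)

    def resolved_firefly_sigmas(self) -> tuple[float, float]:
        """(sigma21, sigma22), applying activity scaling where unset."""
        scaled = firefly_sigmas_from_activity(
            self.true_activity, self.sigma11, self.sigma12
        )
        s21 = self.sigma21 if self.sigma21 is not None else scaled[0]
        s22 = self.sigma22 if self.sigma22 is not None else scaled[1]
        return s21, s22

    def with_tbar(self, tbar: float) -> "SimulationConfig":
        """Copy with (alpha, beta) set from the tabulated pair for ``tbar``."""
        alpha, beta = beta_params_for_mean(tbar)
        return replace(self, alpha=alpha, beta=beta)

    def to_dict(self) -> dict:
        """Flat key-value form, one entry per config field (JSON/YAML friendly)."""
        return asdict(self)

    @classmethod
    def from_dict(cls, mapping: dict) -> "SimulationConfig":
        return cls(**mapping)


@dataclass(frozen=True)
class SimulatedExperiment:
    """A simulated replicate set together with its generating ground truth."""

    data: ReplicateSet
    transfection: np.ndarray
    config: SimulationConfig

    @property
    def true_activity(self) -> float:
        return self.config.true_activity


def simulate_experiment(
    config: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> SimulatedExperiment:
    """Simulate one dual-reporter experiment of ``config.n`` replicates.

    If ``rng`` is omitted a generator is created from ``config.seed``, so a
    fixed seed yields a bit-identical experiment.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    t = sample_transfection(config.n, config.alpha, config.beta, rng)
    s21, s22 = config.resolved_firefly_sigmas()
    e_ren = contaminated_normal(config.n, config.sigma11, config.sigma12, config.gamma, rng)
    e_fir = contaminated_normal(config.n, s21, s22, config.gamma, rng)
    renilla = config.r_max * t + e_ren
    firefly = config.true_activity * config.r_max * t + e_fir
    return SimulatedExperiment(
        data=ReplicateSet(renilla=renilla, firefly=firefly),
        transfection=t,
        config=config,
    )
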