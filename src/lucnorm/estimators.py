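"""Activity estimators for dual-reporter luciferase data.

In a dual-luciferase assay the firefly reporter (experimental promoter or
enhancer) and the Renilla reporter (constitutive internal control) are
measured in each replicate.  Both signals scale jointly with transfection
efficiency, so firefly luminescence is expected to be proportional to
Renilla luminescence, F = A·R, and the relative activity ``A`` is the slope
of a line through the origin.  Four estimators of that slope are provided:

``ratio_estimate``
    The prevalent "ratiometric" normalization: the mean of per-replicate
    ratios F_i/R_i.  Weights low- and high-luminescence replicates equally
    and is badly biased when Renilla values approach zero.
``ols_estimate``
    Through-origin ordinary least squares, minimizing vertical errors in F.
``eiv_estimate``
    Errors-in-variables (orthogonal / total least squares) regression,
    minimizing perpendicular distances, acknowledging noise in both
    reporters.  Closed form.
``reiv_estimate``
    Robust errors-in-variables regression: orthogonal residuals passed
    through Tukey's bounded biweight loss with an M-estimated residual
    scale, limiting the influence of outliers on the slope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import optimize

__all__ = [
    "EstimationError",
    "ReplicateSet",
    "ActivityEstimate",
    "RobustParams",
    "ratio_estimate",
    "ols_estimate",
    "eiv_estimate",
    "reiv_estimate",
    "tukey_loss",
    "estimate_scale",
    "orthogonal_residuals",
    "reiv_profile_objective",
    "ESTIMATORS",
]


class EstimationError(ValueError):
    """Raised when an estimator's preconditions are violated or the fit is undefined."""


@dataclass(frozen=True)
class ReplicateSet:
    """Paired firefly/Renilla luminescence vectors for one construct x condition.

    Parameters
    ----------
    renilla : array-like
        Renilla (control reporter) luminescence per replicate, in RLU.
    firefly : array-like
        Firefly (experimental reporter) luminescence per replicate, in RLU.

    Negative values are permitted: additive measurement noise can drive
    luminescence readings below zero.
    """

    renilla: np.ndarray
    firefly: np.ndarray

    def __post_init__(self) -> None:
        ren = np.asarray(self.renilla, dtype=float)
        fir = np.asarray(self.firefly, dtype=float)
        if ren.ndim != 1 or fir.ndim != 1:
            raise ValueError("renilla and firefly must be one-dimensional vectors")
        if ren.shape != fir.shape:
            raise ValueError(
                f"renilla (n={ren.size}) and firefly (n={fir.size}) must have equal length"
            )
        if ren.size < 1:
            raise ValueError("at least one replicate is required")
        if not (np.all(np.isfinite(ren)) and np.all(np.isfinite(fir))):
            raise ValueError("luminescence values must be finite")
        object.__setattr__(self, "renilla", ren)
        object.__setattr__(self, "firefly", fir)

    @property
    def n(self) -> int:
        """Number of replicates."""
        return int(self.renilla.size)


@dataclass
class ActivityEstimate:
    """Estimated relative activity (slope of F = A·R).

    Attributes
    ----------
    activity : float
        The dimensionless slope estimate.
    method : str
        Label of the estimator used ("ratio", "ols", "eiv", "reiv").
    scale : float, optional
        Robust residual scale in RLU (robust estimator only).
    ci_lower, ci_upper : float, optional
        Confidence-interval bounds.  The basic bootstrap does not guarantee
        that the point estimate lies inside the interval.
    converged : bool
        False when an iterative fit exhausted its evaluation budget.
    degenerate : bool
        True when the robust scale equation has no positive root (e.g. the
        data are exactly collinear), in which case ``scale`` is 0.
    """

    activity: float
    method: str
    scale: Optional[float] = None
    ci_lower: Optional[float] = None
    ci_upper: Optional[float] = None
    converged: bool = True
    degenerate: bool = False


@dataclass(frozen=True)
class RobustParams:
    """Tuning constants for the robust errors-in-variables fit.

    ``c_rho`` is the Tukey biweight tuning constant of the loss (4.7,
    ~95% Gaussian efficiency for location); ``c_chi`` the constant of the
    scale equation (1.56); ``kappa`` the scale-equation target (0.05).
    ``xtol_rel`` and ``maxeval`` bound the slope optimization.
    """

    c_rho: float = 4.7
    c_chi: float = 1.56
    kappa: float = 0.05
    xtol_rel: float = 1e-7
    maxeval: int = 1000

    def __post_init__(self) -> None:
        if self.c_rho <= 0 or self.c_chi <= 0:
            raise ValueError("Tukey tuning constants must be positive")
        if not 0 < self.kappa < self.c_chi**2 / 6:
            raise ValueError(
                f"kappa must lie in (0, c_chi^2/6) = (0, {self.c_chi ** 2 / 6:g})"
            )
        if self.xtol_rel <= 0 or self.maxeval < 1:
            raise ValueError("xtol_rel must be positive and maxeval >= 1")


def tukey_loss(t, c: float):
    """Tukey's biweight loss rho(t) = t²/6·(3 − 3t²/c² + t⁴/c⁴), clamped at c²/6.

    Even, non-decreasing in |t| and bounded by c²/6 for |t| > c, so any
    single point's contribution to a sum of losses is capped.  Accepts
    scalars or arrays.
    """
    if c <= 0:
        raise ValueError("tuning constant c must be positive")
    t = np.asarray(t, dtype=float)
    u = (t / c) ** 2
    inside = t * t / 6.0 * (3.0 - 3.0 * u + u * u)
    out = np.where(np.abs(t) <= c, inside, c * c / 6.0)
    return out if out.ndim else float(out)


def orthogonal_residuals(activity: float, data: ReplicateSet) -> np.ndarray:
    """Signed perpendicular distances of (R_i, F_i) from the line F = activity·R."""
    return (data.firefly - activity * data.renilla) / np.sqrt(1.0 + activity**2)


def ratio_estimate(data: ReplicateSet) -> ActivityEstimate:
    """Ratiometric normalization: the mean of per-replicate ratios F_i/R_i.

    All replicates enter unfiltered; negative or near-zero Renilla values
    produce the wild ratios that make this method unreliable at low
    transfection efficiency.  An exactly zero Renilla value is an error.
    """
    zero = np.flatnonzero(data.renilla == 0.0)
    if zero.size:
        raise EstimationError(
            f"Renilla luminescence is exactly zero at replicate index {zero[0]}; "
            "the ratio F/R is undefined"
        )
    return ActivityEstimate(
        activity=float(np.mean(data.firefly / data.renilla)), method="ratio"
    )


def ols_estimate(data: ReplicateSet) -> ActivityEstimate:
    """Through-origin ordinary least squares slope, Σ F_i R_i / Σ R_i²."""
    sxx = float(np.dot(data.renilla, data.renilla))
    if sxx == 0.0:
        raise EstimationError("all Renilla values are zero; through-origin slope undefined")
    return ActivityEstimate(
        activity=float(np.dot(data.firefly, data.renilla) / sxx), method="ols"
    )


def _eiv_objective(a: float, sxx: float, syy: float, sxy: float) -> float:
    # sum of squared perpendicular distances for the line F = aR
    return (syy - 2.0 * a * sxy + a * a * sxx) / (1.0 + a * a)


def eiv_estimate(data: ReplicateSet) -> ActivityEstimate:
    """Errors-in-variables (orthogonal) regression slope through the origin.

    Minimizes Σ (F_i − A·R_i)²/(1+A²), the squared perpendicular distances.
    The stationary points solve Sxy·A² + (Sxx − Syy)·A − Sxy = 0 with
    Sxx = ΣR², Syy = ΣF², Sxy = ΣRF; the root with the smaller objective is
    returned.
    """
    r, f = data.renilla, data.firefly
    sxx = float(np.dot(r, r))
    syy = float(np.dot(f, f))
    sxy = float(np.dot(r, f))
    if sxy == 0.0:
        # objective reduces to (Syy + A² Sxx)/(1+A²): monotone between Syy
        # (at A=0) and Sxx (as |A| grows); finite minimum only if Sxx > Syy
        if sxx > syy:
            return ActivityEstimate(activity=0.0, method="eiv")
        raise EstimationError(
            "orientation undefined: perpendicular objective has no finite minimizing slope"
        )
    disc = float(np.hypot(sxx - syy, 2.0 * sxy))
    roots = ((syy - sxx) + disc) / (2.0 * sxy), ((syy - sxx) - disc) / (2.0 * sxy)
    vals = [_eiv_objective(a, sxx, syy, sxy) for a in roots]
    if vals[0] == vals[1]:
        raise EstimationError("orientation undefined: both stationary slopes are equally good")
    return ActivityEstimate(activity=float(roots[int(vals[1] < vals[0])]), method="eiv")


def estimate_scale(
    orth_residuals: np.ndarray, params: RobustParams = RobustParams()
) -> tuple[float, bool]:
    """M-estimate of the residual scale S, solving n⁻¹ Σ χ(r_i/S) = κ.

    χ is Tukey's loss with tuning constant ``params.c_chi``.  The left-hand
    side is non-increasing in S, from (fraction of nonzero residuals)·c²/6
    as S → 0⁺ down to 0 as S → ∞, so a unique positive root exists iff that
    limit exceeds κ.  When it does not (e.g. all residuals zero), the fit is
    degenerate and (0.0, True) is returned.

    Returns
    -------
    (scale, degenerate) : tuple of float and bool
    """
    r = np.abs(np.asarray(orth_residuals, dtype=float))
    n = r.size
    if n < 1:
        raise ValueError("at least one residual is required")
    rmax = float(r.max())
    limit0 = np.count_nonzero(r) / n * params.c_chi**2 / 6.0
    if rmax == 0.0 or limit0 <= params.kappa:
        return 0.0, True

    def lhs_minus_kappa(s: float) -> float:
        return float(np.mean(tukey_loss(r / s, params.c_chi))) - params.kappa

    lo = rmax * 1e-12
    hi = max(rmax, np.finfo(float).tiny)
    for _ in range(200):
        if lhs_minus_kappa(hi) < 0.0:
            break
        hi *= 2.0
    else:  # pragma: no cover - unreachable: lhs -> 0 as S -> inf
        raise RuntimeError("failed to bracket the scale equation")
    s = optimize.brentq(lhs_minus_kappa, lo, hi, xtol=1e-12 * hi, rtol=1e-12)
    return float(s), False


def reiv_objective(
    activity: float,
    data: ReplicateSet,
    scale: float,
    params: RobustParams = RobustParams(),
) -> float:
    """The robust loss Σ ρ(r_i(A)/S) at a given slope and fixed scale S."""
    if scale <= 0:
        raise ValueError("scale must be positive")
    r = orthogonal_residuals(activity, data)
    return float(np.sum(tukey_loss(r / scale, params.c_rho)))


def _scale_profile(a: float, data: ReplicateSet, params: RobustParams) -> float:
    """S(A): the M-scale of the orthogonal residuals at slope A (0 if degenerate)."""
    return estimate_scale(orthogonal_residuals(a, data), params)[0]


def _scan_scale_profile(
    a_center: float, data: ReplicateSet, params: RobustParams, n_grid: int = 128
) -> float:
    """Coarse minimizer of S(A) over a wide slope grid around ``a_center``.

    The M-scale profile can be multimodal when outliers form their own
    near-collinear cluster, so the scan brackets the global basin before
    local refinement.  Solved for all grid slopes at once by vectorized
    bisection of the scale equation.
    """
    grid = np.sign(a_center) * np.logspace(
        np.log10(abs(a_center) / 20.0), np.log10(abs(a_center) * 20.0), n_grid
    )
    resid = np.abs(
        (data.firefly[None, :] - grid[:, None] * data.renilla[None, :])
        / np.sqrt(1.0 + grid * grid)[:, None]
    )
    rmax = resid.max(axis=1)
    n = data.n
    degenerate = (rmax == 0.0) | (
        np.count_nonzero(resid, axis=1) / n * params.c_chi**2 / 6.0 <= params.kappa
    )
    if degenerate.any():
        # an (effectively) exact fit of most points: scale 0 is the minimum
        return float(grid[int(np.argmax(degenerate))])
    lo = np.full_like(rmax, np.finfo(float).tiny)
    hi = np.maximum(rmax, 1.0)
    # expand upper bounds until mean chi < kappa everywhere
    for _ in range(200):
        too_low = (
            np.mean(tukey_loss(resid / hi[:, None], params.c_chi), axis=1) >= params.kappa
        )
        if not too_low.any():
            break
        hi[too_low] *= 2.0
    for _ in range(60):  # bisection: ~18 decimal digits are not needed here
        mid = 0.5 * (lo + hi)
        high_side = (
            np.mean(tukey_loss(resid / mid[:, None], params.c_chi), axis=1) > params.kappa
        )
        lo = np.where(high_side, mid, lo)
        hi = np.where(high_side, hi, mid)
    s_grid = 0.5 * (lo + hi)
    return float(grid[int(np.argmin(s_grid))])


def reiv_estimate(
    data: ReplicateSet, params: RobustParams = RobustParams()
) -> ActivityEstimate:
    """Robust errors-in-variables slope via Tukey-biweight M-estimation.

    Estimates the slope A of F = A·R by minimizing
    Σ ρ((F_i − A·R_i)/(S·√(1+A²))) with ρ = Tukey's loss
    (c = ``params.c_rho``), where the residual scale S solves the scale
    equation n⁻¹Σχ(r_i/S) = κ (χ = Tukey's loss with c = ``params.c_chi``).

    Because the loss and the scale must be consistent with each other, the
    fit proceeds in two stages, as in MM-estimation: first the
    high-breakdown scale stage locates the slope minimizing the M-scale
    S(A) of the orthogonal residuals (a wide coarse scan followed by local
    refinement, started at the EIV slope); then, with S fixed at that
    minimal scale, the efficient loss Σρ(r_i/S) is minimized locally over
    the slope with relative tolerance ``params.xtol_rel`` and at most
    ``params.maxeval`` evaluations.  The bounded loss caps any single
    point's contribution at c_rho²/6, so gross outliers cannot drag the
    slope.

    Exactly collinear data have no positive scale root; the EIV slope is
    returned with scale 0 and the degenerate flag set.
    """
    if data.n < 2:
        raise EstimationError(
            "robust errors-in-variables requires n >= 2 replicates "
            "(a single point has zero orthogonal residual for any line through it)"
        )
    a0 = eiv_estimate(data).activity
    s0, deg0 = estimate_scale(orthogonal_residuals(a0, data), params)
    if deg0:
        # exactly collinear data: the EIV line is a perfect robust fit
        return ActivityEstimate(
            activity=a0, method="reiv", scale=0.0, converged=True, degenerate=True
        )

    # stage 1: S-estimation -- slope minimizing the M-scale of the residuals
    a_scan = a0 if a0 == 0.0 else _scan_scale_profile(a0, data, params)
    lo, hi = sorted((a_scan / 1.1, a_scan * 1.1)) if a_scan != 0.0 else (-1.0, 1.0)
    res_s = optimize.minimize_scalar(
        lambda x: _scale_profile(float(x), data, params),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": params.xtol_rel * max(1.0, abs(a_scan)),
                 "maxiter": params.maxeval},
    )
    a_s = float(res_s.x) if res_s.fun <= _scale_profile(a_scan, data, params) else a_scan
    s_hat, degenerate = estimate_scale(orthogonal_residuals(a_s, data), params)
    if degenerate:
        return ActivityEstimate(
            activity=a_s, method="reiv", scale=0.0, converged=True, degenerate=True
        )

    # stage 2: efficient M-step at fixed scale, local around the S-slope
    res_m = optimize.minimize(
        lambda x: reiv_objective(float(x[0]), data, s_hat, params),
        x0=np.array([a_s]),
        method="Powell",
        options={"xtol": params.xtol_rel, "ftol": params.xtol_rel,
                 "maxfev": params.maxeval},
    )
    a_hat = float(np.atleast_1d(res_m.x)[0])
    converged = bool(res_s.success) and bool(res_m.success)
    if res_m.fun > reiv_objective(a_s, data, s_hat, params):
        a_hat = a_s  # keep the S-stage slope if the polish wandered uphill
    return ActivityEstimate(
        activity=a_hat, method="reiv", scale=s_hat, converged=converged,
        degenerate=degenerate,
    )


#: Registry mapping estimator identifiers to their functions.
ESTIMATORS = {
    "ratio": ratio_estimate,
    "ols": ols_estimate,
    "eiv": eiv_estimate,
    "reiv": reiv_estimate,
}
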