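# Methods

## Model

A dual-luciferase experiment yields N replicate pairs (Rᵢ, Fᵢ) of Renilla
(internal control) and firefly (experimental reporter) luminescence, in
relative luminescence units (RLU). Both signals scale jointly with the
per-sample transfection efficiency, so the structural model is a line
through the origin,

    F = A · R,

and the relative activity A — the quantity every estimator targets — is
its slope. None of the estimators fit an intercept: the structural model
has none, and a nonzero intercept would correspond to reporter-independent
background luminescence, which the assay's blank subtraction is assumed to
have removed.

## Estimators

**Ratiometric.** Â = N⁻¹ΣFᵢ/Rᵢ, the field's prevalent method, included as
the baseline being evaluated. It is applied unconditionally to all
replicates; an exactly zero Rᵢ is an error, while negative Renilla values
(possible under additive noise) enter as-is and produce the wild ratios
that make the method unreliable. No filtering is applied, deliberately:
the estimator is reproduced as practitioners use it.

**Through-origin OLS.** Â = ΣFᵢRᵢ/ΣRᵢ², minimizing vertical squared
error. Implicitly weights high-luminescence replicates more, avoiding the
ratio method's main defect, but assumes R is noise-free.

**Errors-in-variables (EIV).** Minimizes the squared perpendicular
distances Σ(Fᵢ − ARᵢ)²/(1+A²), acknowledging noise in both reporters
(orthogonal / total least squares through the origin). The stationary
condition is the quadratic Sxy·A² + (Sxx−Syy)·A − Sxy = 0 with Sxx = ΣR²,
Syy = ΣF², Sxy = ΣRF; of its two roots (which correspond to perpendicular
orientations) the one with the smaller objective is returned. Degenerate
inputs — Sxy = 0 with Syy ≥ Sxx — leave the orientation undefined or
vertical and raise an error rather than return an arbitrary slope.

**Robust EIV (REIV).** Luminescence data contain occasional gross
outliers. REIV bounds their influence by replacing the squared orthogonal
residual with Tukey's biweight loss

    ρ(t) = t²/6 · (3 − 3t²/c² + t⁴/c⁴)  for |t| ≤ c,   ρ(t) = c²/6 beyond,

so any single point's contribution is capped at c²/6. The fit minimizes
Σ ρ(rᵢ(A)/S) over A, where rᵢ(A) = (Fᵢ − ARᵢ)/√(1+A²) is the signed
orthogonal residual and S is a robust residual scale (RLU) defined
implicitly by the M-scale equation

    n⁻¹ Σ χ(rᵢ/S) = κ,   χ = Tukey's loss with c_χ = 1.56,   κ = 0.05,

with the loss itself using c_ρ = 4.7. Two constants because the two roles
differ: the tight c_χ makes the scale resistant to outliers, the wide c_ρ
keeps the slope efficient on clean Gaussian data.

### How the REIV optimum is found

The loss and the scale must be mutually consistent, and this coupling is
treacherous: if S is naively re-solved inside the loss at every candidate
slope, a badly wrong slope whose residuals happen to be homogeneous in
magnitude (for example a near-vertical line through data clustered at
similar R) gets a generously inflated scale and therefore a spuriously
small loss. We therefore fit in two stages, the classic S-then-M
(MM-estimation) construction:

1. **Scale stage.** Find the slope minimizing the M-scale S(A) of the
   orthogonal residuals. S(A) is itself resistant to outliers, and its
   minimizer is a high-breakdown (if inefficient) slope estimate. Because
   an outlier cluster can carve a second local basin into S(A), the stage
   first scans a wide slope grid (256 log-spaced points spanning a factor
   of 20 on either side of the EIV start, all scale equations solved at
   once by vectorized bisection) and then refines the best grid point by
   bounded scalar minimization.
2. **Efficiency stage.** Fix S at the minimal scale S* and minimize
   Σρ(rᵢ(A)/S*) locally around the scale-stage slope (derivative-free,
   relative tolerance 1e−7, at most 1000 evaluations). With S* held fixed,
   distant wrong-slope basins are correctly penalized — residuals there
   are huge on the S* scale and simply clamp.

The scale equation itself is solved by bracketed Brent root-finding; its
left side decreases monotonically in S from (fraction of nonzero
residuals)·c_χ²/6 to 0, so a positive root exists iff that limit exceeds
κ. When it does not — exactly collinear data, or a fit passing exactly
through more than 1 − 6κ/c_χ² ≈ 88% of the points — the fit is flagged
degenerate: S = 0 is returned with the EIV slope (collinear data should be
a fixed point of the robust fit, not an error).

Tukey's polynomial is clamped to the constant c²/6 for |t| > c; without
the clamp the printed polynomial is unbounded and the loss would lose
exactly the boundedness that makes the estimator robust.

## Confidence intervals

Nonparametric case resampling of replicate pairs (Rᵢ, Fᵢ), 999 resamples
by default, summarized by the **basic bootstrap** interval
(2Â − q₁₋α/₂, 2Â − qα/₂) with q the empirical quantiles (linear
interpolation) of the resampled slopes. The `basic_positive` variant
clamps the lower bound at 0, since relative activities are physically
non-negative. Resamples on which an estimator fails (e.g. a ratio
resample drawing a zero Renilla value) are dropped and counted, and the
interval is refused if fewer than half succeed. A coverage study in the
test suite (500 clean simulations at N=10, checked against an independent
3000-run oracle) puts the realized coverage of the nominal 95% EIV
interval at ~90%: the basic bootstrap undercovers at small n, a known
property worth remembering when interpreting intervals from 10-replicate
experiments.

## Simulator

Each replicate draws a transfection efficiency tᵢ ~ Beta(α, β); the
tabulated (α, β) pairs (2,18), (2,6), (2,2), (6,2), (18,2) give mean
efficiencies t̄ = 0.1, 0.25, 0.5, 0.75, 0.9, with the Beta coefficient of
variation rising as t̄ falls — low-efficiency experiments are noisier, as
in real cells. Luminescences are

    Rᵢ = r_max·tᵢ + CN(σ₁₁², σ₁₂², γ),
    Fᵢ = A·r_max·tᵢ + CN(σ₂₁², σ₂₂², γ),

where CN(σ₁², σ₂², γ) = (1−γ)N(0,σ₁²) + γN(0,σ₂²) is a contaminated
normal: with frequency γ (default 0.05, chosen independently per
measurement) an error comes from the wider σ₂ component, modeling gross
outliers; σ₂ = σ₁ recovers an outlier-free Gaussian. Firefly error SDs
default to activity scaling, σ₂₁ = Aσ₁₁ and σ₂₂ = Aσ₁₂, because the
firefly signal is A times larger; both can be overridden. Renilla errors,
firefly errors and tᵢ are mutually independent.

Defaults: A = 10, N = 10, t̄ = 0.25, σ₁₁ = σ₁₂ = 3, γ = 0.05, and
r_max = 20 RLU. r_max sets the RLU scale of a maximally transfected
sample; 20 RLU matches the scale of typical low-efficiency myeloid-line
measurements and makes σ₁₁ = 3 a substantial relative error at low t̄. It
is an exposed parameter, and simulated conclusions that depend on the
absolute RLU scale (notably the size of the ratiometric bias) move with
it.

What the simulator does *not* model: plate or batch effects, correlated
firefly/Renilla noise, lognormal (multiplicative) error, or luminometer
saturation. Passing tests therefore demonstrate correct behavior under
additive contaminated-Gaussian noise with Beta-distributed efficiency —
not under every failure mode of real instruments.

## Evaluation metrics

Over M = 300 simulation repeats with true activity A and estimates Aₖ:

* **P90 relative bias** — 90th percentile of |A − Aₖ|/A (accuracy).
* **Relative MAD** — median(|Aₖ − median(Aₖ)|)/A (precision; no 1.4826
  consistency factor, and normalized by the true A rather than by
  median(Aₖ) so that it parallels the bias normalization).
* **Zamar criterion** — mean of 1 − |1 + AₖA|/√((1+Aₖ²)(1+A²)), the
  sine-squared-like discrepancy between the fitted and true line
  *directions*: 0 at perfect recovery, 1 at the perpendicular slope −1/A,
  invariant under rotations of the (R, F) plane and therefore comparable
  across activity levels where slope-based measures blow up. The
  denominator is computed as the square root of the product so both
  identities hold exactly in floating point.

The benchmark evaluates all four estimators on the *same* m simulated
datasets per level of the swept factor (t̄, N, A, σ₁₁ or σ₁₂), with one
RNG substream per (level, repeat) spawned from the master seed —
reproducible and parallelizable without changing any draw.

## Numerical choices and problem sizes

* EIV root selection by objective value; exact ties raise (orientation
  undefined).
* Scale-equation root isolated in [max|r|·10⁻¹², expanding upper bound],
  Brent to ~12 digits; the grid scan uses 60 bisection steps.
* Degenerate-scale threshold uses ≤ κ (a root at S → 0⁺ counts as
  degenerate).
* Bootstrap and benchmark seeds derive from `numpy.random.SeedSequence`
  spawning, so group order, not call order, determines each stream.
* Test-suite simulation sizes — 300 repeats per benchmark cell, 500
  coverage runs, 10⁵–10⁶ draws for distributional checks — keep the whole
  suite under a minute of CPU while leaving Monte-Carlo standard errors
  well inside the asserted tolerances.

## Known limitations

* The ratio estimator's sampling distribution has no finite moments when
  P(R ≈ 0) > 0; its simulated bias summaries are accordingly seed-noisy
  at low t̄.
* REIV's two-stage search is deterministic but not a certified global
  optimizer; pathological fixtures with several equally sized collinear
  clusters could settle in a non-global basin.
* The basic bootstrap undercovers at N ≲ 10 (see above); BCa or
  studentized intervals are out of scope.
* Between-condition inference (e.g. dividing by a reference construct's
  slope) does not propagate the reference's uncertainty.
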