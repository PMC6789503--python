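# lucnorm

Regression-based normalization of dual-reporter (firefly/Renilla)
luciferase assay data.

## The problem

Transient luciferase reporter assays measure promoter or enhancer activity
by placing a firefly *luciferase* gene under the control of the regulatory
element of interest, with a co-transfected Renilla *luciferase* construct
as a constitutive internal control. Transfection efficiency and other
experimental errors vary strongly from sample to sample — especially in
hard-to-transfect cell types — and affect both reporters jointly, so
firefly luminescence F is expected to be proportional to Renilla
luminescence R:

    F = A · R

where the slope **A** is the relative activity of the experimental
construct. The prevalent "ratiometric" normalization estimates A as the
mean of per-replicate ratios,

    Â_ratio = (1/N) Σᵢ Fᵢ/Rᵢ,

which weights low- and high-luminescence replicates equally even though
ratios of small, noisy luminescences are wildly unreliable. At low
transfection efficiency this produces heavily biased activity estimates
that do **not** improve with sample size.

`lucnorm` provides four estimators of A, all fitting lines through the
origin:

| method  | estimate of A                               | robust to R-noise | robust to outliers |
|---------|---------------------------------------------|-------------------|--------------------|
| `ratio` | mean of Fᵢ/Rᵢ                               | no                | no                 |
| `ols`   | through-origin least squares ΣFᵢRᵢ/ΣRᵢ²     | no                | no                 |
| `eiv`   | errors-in-variables (orthogonal) regression | yes               | no                 |
| `reiv`  | robust EIV: Tukey-biweight M-estimation of the orthogonal fit | yes | yes |

plus basic-bootstrap confidence intervals (999 resamples of replicate
pairs), a parameterized simulator of dual-reporter experiments with known
ground truth, and a simulation benchmark comparing the methods by the
Zamar criterion, the 90th percentile of relative bias, and the relative
median absolute deviation. See `docs/methods.md` for the statistical
details.

## Worked example

Simulate one experiment (10 replicates, true activity 10, 25% mean
transfection efficiency) and normalize it with the robust estimator:

```sh
$ lucnorm simulate -o demo.csv --tbar 0.25 --true-activity 10 --n 10 --seed 11
$ head -3 demo.csv
Luc,Ren,Construct
15.969790859638524,7.3194328284626913,sim
63.630669546447535,5.570235334793507,sim

$ lucnorm normalize demo.csv -o demo_norm.csv --method reiv --ci boot-positive --seed 11
Construct     slope  ci_lower  ci_upper  n_replicates method  converged status
      sim 13.854039       0.0 17.969628            10   reiv       True     ok
```

The `slope` column is the estimated relative activity: this noisy
10-replicate experiment estimates Â ≈ 13.9 against a generating truth of
10 (the truth is recorded in `demo.csv.truth.json`). `ci_lower`/`ci_upper`
are the 95% basic-bootstrap bounds; `boot-positive` clamps the lower bound
at zero since activities are physically non-negative. Input files follow a
fixed CSV layout — columns `Luc`, `Ren`, `Construct`, then one column per
experimental condition — and `normalize` fits one slope per observed
construct × condition combination.

Comparing all four methods across transfection efficiencies:

```sh
$ lucnorm benchmark --sweep tbar --values 0.1,0.9 --repeats 100 --seed 1 --out bench.csv
```

| tbar | method | zamar | P90 relative bias | relative MAD |
|------|--------|-------|-------------------|--------------|
| 0.1  | ratio  | 0.043 | 6.43              | 1.09         |
| 0.1  | ols    | 0.096 | 1.04              | 0.21         |
| 0.1  | eiv    | 0.003 | 11.3              | 1.26         |
| 0.1  | reiv   | 0.003 | 11.5              | 1.28         |
| 0.9  | ratio  | 0.000 | 0.145             | 0.053        |
| 0.9  | ols    | 0.000 | 0.111             | 0.046        |
| 0.9  | eiv    | 0.000 | 0.143             | 0.049        |
| 0.9  | reiv   | 0.000 | 0.143             | 0.049        |

At 90% efficiency every method works; at 10% efficiency all struggle on
this RLU scale, and the angle-based Zamar criterion (0 = perfect recovery
of the fitted line, 1 = perpendicular) shows the errors-in-variables fits
recovering the line orientation far better than their slope-scale bias
suggests. Each method is evaluated on the exact same simulated datasets.

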