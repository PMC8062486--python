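# Methods

## The growth model

Lens dry weight (LDW, mg) is modelled as an asymptotic logistic function of
age,

```
LDW(A) = a · 10^(−b/(A + c)),        log10 LDW = log10 a − b/(A + c)
```

where `A` is postnatal age in days, `a` the asymptotic lens weight (mg),
`b` the growth-rate constant (days; larger `b` = slower approach to the
asymptote) and `c` the prenatal growth time (days), so `A + c` is elapsed
growth time. The curve is strictly increasing in age and bounded by `a`;
its inverse `A = b / log10(a/LDW) − c` is defined for `0 < LDW < a` only —
a lens at or above the assumed asymptote has no finite age under that
curve, and `age_bias_table` reports such rows as NaN rather than failing.

`c` is **fixed at 32 days** throughout the fitting machinery. Published
asymptotes are only comparable when computed on a common `c`, and the
curves this package targets all carry `(A + 32)`; `c` remains a
constructor argument so other conventions stay usable, but it is never
estimated (estimating `a`, `b` and `c` jointly from field data of this
size is poorly conditioned, and all comparisons here are at fixed `c`).

Juvenile age from body weight uses the linear relation
`W = wi + r(A − 21)` with defaults `wi = 200 g` (weaning weight),
`r = 9.77 g/day`, weaning at 21 days. The relation is linear only for
juveniles, so estimation is refused at `W ≥ 500 g` (roughly half adult
weight); weights below `wi` are extrapolations below weaning and are
flagged. Ages produced this way carry an `estimated` provenance flag,
mirroring field datasets that mix exactly-known (cage-born) and
weight-estimated (trapped) ages. Estimated-age records are fitted exactly
like known-age records; the flag exists for sensitivity analyses.

Ages are real-valued days everywhere; rounding is presentation only.
Units are fixed (lens mg, body weight g, age days) with no auto-detection.

## Constrained least squares

For two groups `g ∈ {1, 2}` the model is
`y_i = a_{g(i)} · 10^(−b_{g(i)}/(t_i + c)) + ε_i`, with optional equality
constraints `a_1 = a_2` and/or `b_1 = b_2` imposed by parameter packing
(shared parameters occupy one slot of the optimisation vector). The four
on/off combinations are the candidate Models 1–4 (1: both shared, 2:
neither, 3: `a` shared, 4: `b` shared).

Residuals are minimised by trust-region-reflective least squares
(`scipy.optimize.least_squares`) with an analytic Jacobian, positivity
bounds `a, b > 0`, tolerances `ftol=1e−12`, `xtol=1e−10`, and a budget of
200·(p+1) function evaluations. Starting values: `a₀ = 1.05 × max`
observed lens weight (per group, pooled when shared), so the asymptote
starts above every observation; `b₀ = 60 d`, near typical published rates.
A failed optimisation returns `converged=False` rather than silently wrong
numbers; degenerate designs (all ages or all weights identical) and
under-determined fits (< 3 observations per free parameter) are rejected
up front.

**Fitting scale.** The default minimises residuals on the mg scale. A
Gaussian likelihood on mg with residual sd ≈ 19 mg reproduces the AICc
magnitudes (~2500 at n=285) that make the model ranking meaningful;
the log10-scale option is provided because the linearised form is standard
in the lens-growth literature, and on noiseless data both scales recover
identical parameters. One pooled residual variance is used per model (not
per group), matching the single-sd parameter count below.

**Uncertainty.** Standard errors come from the curvature of the
least-squares surface: `cov = s²(JᵀJ)⁻¹` with `s² = RSS/(n − p)`. The SVD
of `JᵀJ` guards against rank deficiency and names the unidentifiable
parameter in the error. The log-likelihood reported for model selection is
the Gaussian log-likelihood at the ML variance `RSS/n`,
`ℓ = −n/2 (ln 2π + ln(RSS/n) + 1)`, the standard choice when ranking
least-squares fits by information criteria.

## Model selection

`AICc = −2ℓ + 2K + 2K(K+1)/(n − K − 1)` with `K` = number of distinct
curve parameters **plus one** for the residual sd: K = 3/5/4/4 for
Models 1/2/3/4 with two groups. Akaike weights are
`exp(−Δᵢ/2)/Σ exp(−Δⱼ/2)`; models within 2 AICc units of the best are
flagged equally plausible, and the table never discards a model. A
candidate that fails to converge keeps its row with NaN criteria and is
excluded from the weights.

One structural fact worth knowing when reading the table: Model 2 nests
Model 4, so under a Model-4 truth the AICc gap between them is (penalty −
a χ²₂-distributed improvement) and Model 4's *single-model* weight
converges to ≈ 0.7 rather than 1 as noise shrinks, with Model 2 taking the
rest — the shared-asymptote models' combined weight is what vanishes. The
tests assert exactly that structure.

## Overlap of asymptote distributions

To compare asymptotes across populations without shared raw data, `n_sim =
1000` draws are taken from each asymptote's `Normal(estimate, SE)` sampling
distribution (for a population whose SE was never published, the locally
estimated SE is borrowed — a surrogate the user must flag as such). The
overlap index is

```
η = ∫ min(f₁, f₂) dx   ∈ [0, 1]
```

with `f₁, f₂` Gaussian KDEs. Bandwidths use the Silverman rule-of-thumb
`h = 0.9 · min(sd, IQR/1.34) · n^(−1/5)` — the default of R's `density()`,
so η here is comparable with analyses done with the R `overlapping`
package — evaluated on a shared 1024-point grid spanning the pooled sample
range padded by 3·max(h). Both the bandwidth rule and the grid are
arguments, since η is mildly dialect-dependent. η is exactly symmetric
(shared grid), shift-invariant, and clipped to [0, 1] against quadrature
round-off. For two equal-variance normals separated by `d` sd the analytic
value is `2Φ(−d/2)`, used as an independent oracle in the tests. The
normality of the *sampling distribution* of `a` is an assumption of the
simulation step; the overlap estimator itself is distribution-free.

## Cross-validation

Repeated (default 100×) 10-fold cross-validation of the selected model.
Folds are stratified by group so every training set contains both
subspecies and can identify group-specific parameters (a degenerate
partition is redrawn, at most 10 times). Per repeat, one
`R² = 1 − Σ(o−p)²/Σ(o−ō)²` is computed on the **pooled held-out
predictions** — not averaged over folds, which gives systematically
different values — and the mean over repeats is reported. R² is evaluated
on the fitting scale (mg by default). All randomness derives from one seed
via `numpy.random.SeedSequence` spawning.

## The synthetic-data generator

The generator emulates the study design the pipeline was built for: groups
Oca (n=112, a=240 mg) and Occ (n=173, a=273 mg), shared b=64.9 d, c=32 d;
ages drawn from a three-class mixture (<90 d, 90–365 d, 365–1392 d with
probabilities 138/285, 76/285, 71/285; uniform within class — only class
counts, not a density, are known for the real data); additive Gaussian
lens-weight noise, default sd 19 mg, back-solved from the AICc magnitude a
Gaussian mg-scale likelihood implies at n=285 (no residual spread is
published). Noise is truncated by *resampling* until the lens weight
exceeds 0.1 mg, keeping the distribution honestly
Gaussian-conditional-on-positive rather than clipped. Juvenile body
weights follow the linear weaning relation, so animals past ~52 days
naturally exceed the 500 g cap and exercise the refusal path.

What the generator does **not** emulate: heteroscedastic lens-weight error
(real lens residuals likely grow with the mean; the additive 19 mg noise is
a deliberate simplification), group-specific age structures (the pooled
class mixture is applied to both subspecies), trapping/mortality/disease
processes, and measurement error in age itself. Passing tests therefore
demonstrate correctness of the estimators under the stated noise model,
not robustness to every feature of field data.

Two numerical consequences of the design, measured and accepted rather
than hidden:

- **Truncation bias.** Resampling negative noise shifts juvenile lens
  weights upward, a fixed model misspecification worth about −1 mg in the
  fitted asymptotes and −1 d in `b`. At the study size (SEs ≈ 3.6–4 mg)
  this is negligible; at n=5000 it exceeds the shrinking SEs, so the
  large-n parameter-coverage test runs on adult-only ages where the
  truncation never triggers (juvenile mean lens weights sit within 1 sd of
  zero; adult means are > 3.7 sd above it).
- **Finite-sample NLS bias.** Even without truncation, the asymptote
  estimates carry a small (≈ −0.5 mg) nonlinearity bias at the study size;
  medians over 100 replicates land at 239/272 mg against generating values
  240/273.

## Problem sizes

Defaults were chosen so every analysis runs interactively on one core: the
full test suite performs several hundred NLS fits (n=285 each, ~5 ms per
fit) plus 100 fits at n=5000, and finishes in well under a minute; the
acceptance script's 100-replicate recovery protocol takes ~2 s.

## Known limitations

- `c` is never estimated; analyses on a different prenatal-offset
  convention must supply their own `c` and refit.
- No robust or heteroscedastic loss; a single pooled residual variance.
- η is reported for the asymptote only: the growth rate `b` varies with
  habitat quality, so cross-population overlap of `b` is not a meaningful
  subspecies comparison and is deliberately not provided.
- The bias tables quantify curve-vs-curve error only; they do not
  propagate parameter uncertainty into the age estimates.
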