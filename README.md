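# lensage

Age determination of European wild rabbits (*Oryctolagus cuniculus*) from
eye-lens dry weight (LDW).

The dry weight of the eye lens accumulates monotonically over a mammal's
life and is largely insensitive to environment, which makes it the standard
age indicator for rabbits and other lagomorphs. Lens growth follows the
asymptotic logistic curve

```
LDW(A) = a · 10^(−b / (A + c))
```

with `A` the postnatal age (days), `a` the asymptotic lens weight (mg), `b`
the growth-rate constant (days) and `c` the prenatal growth offset (days,
fixed at 32 here), so aging a carcass is just inverting the curve:
`A = b / log10(a / LDW) − c`.

The catch: the rabbit's native Iberian range holds two subspecies
(*O. c. cuniculus*, "Occ", and *O. c. algirus*, "Oca") with different
asymptotic lens weights (a ≈ 273 vs 240 mg, shared b ≈ 64.9 d). Using a
single curve — in particular the Australian-calibrated one — systematically
under-ages Oca rabbits, by months for older animals. `lensage` implements
the full analysis that establishes and quantifies this:

- **growth model** — the curve, its inversion, the linear juvenile
  weight-age relation (`A = 21 + (W − 200)/9.77`, refused at ≥ 500 g), and
  cross-curve bias tables;
- **constrained NLS fitting** — estimate `(a, b)` for two groups with
  optional equality constraints on `a` and/or `b`, with standard errors
  from the least-squares curvature;
- **AICc model selection** — rank the four sharing hypotheses (all shared …
  distinct `a`/shared `b`) by small-sample-corrected AIC with Akaike
  weights;
- **cross-validation** — repeated stratified 10-fold CV of the selected
  model, average held-out R²;
- **overlap analysis** — simulate each asymptote's Normal(estimate, SE)
  sampling distribution and compute the kernel-density overlap index
  η ∈ [0, 1] (0 = fully separated);
- **synthetic data** — a generator reproducing the study design (Oca
  n=112 / Occ n=173, three-class age mixture over 17–1392 d, 19 mg additive
  lens-weight noise) so the pipeline is fully testable without the
  undeposited field data.

Intended users: wildlife ecologists and game managers estimating population
age structure from carcasses, and anyone validating a growth-curve-based
aging method across genetic forms of one species.

## Worked example

```python
from lensage import FitSpec, GeneratorConfig, fit_curve, generate_dataset

data = generate_dataset(GeneratorConfig(seed=1))   # 112 Oca + 173 Occ
fit = fit_curve(data, FitSpec(share_a=False, share_b=True))
print(fit.estimates)
```

prints

```
{'a_Oca': 239.59, 'a_Occ': 273.94, 'b': 67.71}
```

(standard errors ≈ 3.7, 3.6 mg and 1.4 d): the two asymptotes generated
into the data (240 and 273 mg) are recovered within one SE each. Running
the model comparison on the same dataset
(`fit_candidate_models(data).to_dataframe()`) gives

```
 model                sharing  K     AICc  dAICc  weight
     4   a by group, b shared  4 2467.632  0.000   0.735
     2 a by group, b by group  5 2469.675  2.043   0.265
     3   a shared, b by group  4 2499.466 31.834   0.000
     1     a shared, b shared  3 2524.591 56.959   0.000
```

— essentially all the evidence sits on the distinct-asymptote models, and
the kernel-density overlap between the two fitted asymptotes' sampling
distributions is η = 0.0000 (complete separation), while the same Occ fit
compared against the Australian asymptote (276 mg, borrowing the local SE)
overlaps at η ≈ 0.77. The scripts in `examples/` walk through each
capability (simulation+fit, model selection, overlap, cross-validation,
age bias) and print these numbers with interpretation.

A thin CLI wraps the same functions:

```sh
lensage simulate --seed 1 --out obs.csv
lensage select obs.csv --out comparison
lensage pipeline --seed 1 --out results/
```

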