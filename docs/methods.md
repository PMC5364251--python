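# Methods

## Model

The package fits the two-factor fixed-effects linear model

```
y_i = β0 + Σ_k α_k A_ik + Σ_l γ_l B_il + Σ_kl δ_kl (AB)_ikl + ε_i
```

for an outcome `y` on two categorical factors A (K levels) and B (L
levels), with homoskedastic errors under the Gaussian family and, more
generally, any GLM mean structure on the same coded columns. The factors
enter through K−1 and L−1 main-effect columns and, optionally,
(K−1)(L−1) interaction columns, under one of three parameterizations
(dummy, effect, weighted effect). All three span the same column space
together with the intercept, so fitted values, residuals, and explained
variance are identical across schemes; only the meaning of individual
coefficients differs.

Weighted effect coding (WEC) is the package's reason to exist. A WEC
main-effect column for level `k` codes 1 at `k`, `−n_k/n_r` at the
omitted level `r`, 0 elsewhere, so each column sums to zero over
observations and the coefficients are deviations of level means from the
count-weighted sample mean. The WEC interaction column for cell `(k, l)`
follows the four-cell pattern (1, `−n_kl/n_{k,rB}`, `−n_kl/n_{rA,l}`,
`+n_kl/n_{rA,rB}`), which makes it exactly orthogonal — as an identity,
not just in expectation — to the intercept and to every WEC main-effect
column of both factors: each pairwise dot product over observations is a
four-term sum of cell-count-weighted ratios that cancels algebraically.
Consequently the intercept and main effects of an identity-link fit are
unchanged when the interaction block is added, and the interaction
coefficient for cell `(k, l)` equals the cell mean minus the additive
model's prediction for that cell.

The published description covers the 2×3 case; the K×L columns here
apply the same four-cell pattern per interaction column. The
generalization is validated by the orthogonality, invariance, and
balanced-collapse property tests rather than by a printed reference
formula.

### Assumptions and caveats

- Orthogonality is a property of the *columns*, so main-effect
  invariance holds for identity-link fits without controls. For
  non-identity links (logit) column orthogonality does not imply
  information orthogonality; the package does not assert invariance
  there, and `verify_invariance` reports the observed change instead.
  Logit coefficients relate to the odds `p/(1−p)`, not to `p`.
- With control variables the interaction columns may correlate with the
  controls, so main effects in a controlled model can differ with and
  without the interaction block. Controls are supported as extra
  columns; completion of omitted categories is not offered for
  controlled fits.
- WEC interaction weights divide by cell counts, so every referenced
  cell must be non-empty; an empty cell raises an error naming the cell.
  Dummy and effect schemes tolerate empty cells.
- By default the weights come from the analysis sample's counts. A
  caller may supply a `TwoWayCellTable` with external (e.g. population)
  counts instead, when the unbalance of the target population rather
  than of the sample is the relevant baseline.

## Estimation

Raw fits use statsmodels OLS/GLM on the assembled columns (QR/SVD-based
solvers, not normal equations); rank is checked beforehand by pivoted QR
with relative tolerance 1e-10, and a deficiency error names the
collinear columns. Grouped fits exploit that all coded predictors are
cell-constant: count-weighted least squares on the cell means reproduces
the observation-level coefficients exactly, from counts and means alone.
Grouped fits report no standard errors (the within-cell variance is not
part of the sufficient statistics) and no R².

Omitted-category completion refits the model with different omitted
levels (grouped route) and takes the union of coefficient sets; the
three interaction cells covered by neither fit follow from the scheme's
sum-to-zero constraints (count-weighted per row and column for WEC,
unweighted for effect coding), propagated one missing cell at a time.
Every doubly-determined value and every constraint is cross-checked at
absolute tolerance 1e-6 (constraint residuals scaled by the counts
involved); disagreement raises, because with correct coding the two
routes agree to machine precision and a larger gap can only signal a
bug.

For the binomial family, fitted probabilities within 1e-6 of 0 or 1
after IRLS are treated as perfect separation (no finite MLE) and raise a
convergence error with iteration diagnostics, since IRLS can otherwise
terminate quietly with diverged parameters.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| `omitted` | `"auto"` (most frequent level) | reference level; the most frequent level gives the best-determined completion. Always overridable. |
| `scheme` | `weighted_effect` | coding scheme; `dummy` and `effect` provided for comparison. |
| rank tolerance | 1e-10 relative | pivoted-QR collinearity threshold. |
| completion tolerance | 1e-6 absolute | refit-vs-constraint cross-check. |
| reproduction tolerance | 0.03 outcome units | see below. |

Level ordering is first appearance in the data unless declared; all
results are keyed by level label, never by position. Rows with missing
outcome, factor, or control values are dropped listwise with a logged
count.

## The built-in reproduction

The bundled fixture holds the printed inputs of the BMI example
(n = 3314, a 2×3 cross of having children by age group with cell sizes
99/1624/531/511/487/62) and the printed coefficient estimates of all
three schemes. The six cell means are reconstructed from the saturated
dummy parameterization — the fitted value of a saturated model in a cell
is the sum of the intercept and the active coefficients, and equals the
observed cell mean — and the effect-coded and WEC columns of both models
are then recomputed by grouped least squares and compared term by term.

The comparison tolerance is 0.03 outcome (BMI) points: the printed
inputs are rounded to two decimals, so each reconstructed cell mean
carries up to ±0.02 of propagated rounding (sums of up to four ±0.005
terms), and count-weighted mixing cannot push a recomputed coefficient
outside the extrema of its input errors. Observed deviations are ≤0.005.
The two hand arithmetic identities of the running example (the
effect-coded fitted childless-young cell, 22.94, and the dummy-coded
childless contrast among the middle-aged, −0.7) are checked as exact
arithmetic on the printed numbers, separately from the tolerance-based
fit comparison.

One printed value is internally inconsistent in the source: the
effect-coded interaction model's middle-age term is printed 0.11 while
the accompanying text derives with 0.21 (the additive model's value).
The recomputation gives 0.105 for the interaction model, consistent with
the printed 0.11; the reproduction report lists both recomputed values
and adjudicates neither. Published t-values and explained variances are
out of reach of this reconstruction (they need the within-cell variance
of the raw survey microdata) and are not reproduced.

## Synthetic data

The generator emulates the structure of unbalanced factorial
observational data: fixed per-cell counts (design, not random), constant
true cell means, homoskedastic normal noise within cells, and an
optional standard-normal control with a linear slope. One seeded
generator stream is consumed cell by cell in label-sorted order, so a
given config is bit-reproducible. `balanced_counterpart` raises all
counts to the maximum cell count for the scheme-collapse tests. The
default study layout for simulation-based tests is the fixture's own
2×3 table (counts 99–1624, BMI-scale means, residual SD 4.0 — a
realistic BMI spread); the Monte-Carlo bias check uses 200 replicates,
bounded by the standard error of the smallest cell (n = 62).

What the generator does not emulate: non-normal or heteroskedastic
noise, missing-data mechanisms, measurement error in self-reports, and
survey weighting. Passing tests therefore establish the algebraic and
statistical properties of the coding and estimators, not robustness to
those real-data features.

## Known limitations

- Two factors only; no three-way cross-classifications, no survey
  weights.
- No interactions between coded factors and continuous covariates.
- Grouped fits carry no uncertainty estimates.
- The effect/WEC completion requires refitting; for dummy coding the
  omitted categories are structurally zero and completion is refused.
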