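# Methods

## Model

`radcatch` fits a two-class discriminant for matrix-valued predictors
with vector covariates. Classes are coded 1 = recurrent, 2 =
non-recurrent throughout. The generative view is:

* covariates `U | Y=k ~ N(φ_k, Ψ)` (q-vector of gene expression);
* images `X | U, Y=k` matrix-normal with mean `μ_k + α ×̄₃ U` and
  separable covariance `Σ₂ ⊗ Σ₁` (`×̄₃` contracts the last axis of the
  `p1 x p2 x q` tensor `α` with `U`).

The Bayes rule under this model is linear in `(U, X_adj)` with
`X_adj = X − α ×̄₃ U`, giving the score
`s = a + γᵀU + ⟨B, X_adj⟩`, `γ = Ψ⁻¹(φ₁ − φ₂)`,
`B = Σ₁⁻¹(μ₁ − μ₂)Σ₂⁻¹`, and the LDA-composition intercept
`a = log(π₁/π₂) − ½⟨B, μ₁+μ₂⟩ − ½γᵀ(φ₁+φ₂)`. Ties (`s = 0`) go to
non-recurrent; the posterior is the logistic transform of `s`.

## Estimation

* **α** — entrywise OLS of within-class-centered `X` on
  within-class-centered `U` (one shared Gram solve for all pixels).
  Rank-deficient covariates raise an error suggesting a ridge
  (`ridge * mean(diag) * I`), which is available but off by default.
* **γ, φ, Ψ** — plug-in class means and pooled (ddof-corrected)
  covariance of `U`; a ridge of `1e-4 * mean(diag)` is added only when
  `Ψ` is near-singular (smallest eigenvalue < 1e-8).
* **Σ₁, Σ₂** — flip-flop moment iteration on within-class residuals
  `E_i` of `X_adj`: `Σ₁ ← (1/(n p2)) Σ E_i Σ₂⁻¹ E_iᵀ`, then
  `Σ₂ ← (1/(n p1)) Σ E_iᵀ Σ₁⁻¹ E_i`, from identity starts, until the
  relative Frobenius change is below 1e-6 (max 100 rounds). The scale
  indeterminacy of a Kronecker product is fixed by `Σ₁[0,0] = 1`
  (absorbed into `Σ₂`). The same conditional ridge applies per iterate.
* **B** — cyclic coordinate descent on
  `½⟨B, Σ₁BΣ₂⟩ − ⟨B, D⟩ + λ‖B‖₁` with
  `D = μ̂₁ − μ̂₂` of `X_adj`; the update is
  `b_ij ← S(D_ij − [Σ₁BΣ₂]_ij + Σ₁_ii Σ₂_jj b_ij, λ)/(Σ₁_ii Σ₂_jj)`
  with `S` the soft-threshold. The quadratic gradient is maintained
  incrementally (numba kernel), convergence is `max |Δb| < 1e-8`
  (budget `10·p1·p2` sweeps; hitting it flags the model and warns).
  Warm starts run along a 50-point log-spaced path from
  `λ_max = max|D|` down to `0.01 λ_max`; `λ ≥ λ_max` gives `B = 0`
  exactly, and padded grid cells can never be selected because their
  `D` entry is identically zero.
* **λ selection** — three rules: `cv` (5-fold stratified CV maximizing
  validation AUC of the intercept-free margin, ties resolved to the
  larger penalty; the statistical default), `sparsity` (the smallest
  path penalty keeping at most `s_target = 10` nonzeros, mirroring a
  fixed ten-feature budget), and `fixed`. The benchmark and acceptance
  runs use the sparsity rule, both for its interpretability (a fixed
  selected-feature budget) and because it is roughly 8x cheaper per fit
  at the 33 x 32 scale; CV is exercised in the unit tests.

With `q = 0` the fit reduces to plain (sparse) tensor discriminant
analysis, and on a `1 x 1` grid to univariate LDA with the MLE pooled
variance — both covered by closed-form oracle tests.

## Covariate selection

Counts are normalized by median-of-ratios size factors (reference
geometric means restricted to all-positive genes; a pseudo-count mode
covers zero-laden panels). Each gene is tested by a Welch two-sample
t-test on `log2(normalized count + 1)`; p-values are BH-corrected and
the `k_select = 30` smallest-q genes become covariates (ties: larger
|log2FC|, then gene id). This stage is a deliberately simple,
fully-specified stand-in for a negative-binomial DE workflow — the
downstream model consumes only the ranked gene list and log2
expression, so the stage is replaceable behind its interface. By
default selection is re-run inside every training split ("nested");
a global-selection mode reproduces protocols that select once on all
patients, which leaks label information into test folds and is logged
as such.

## Evaluation

100 random stratified 67/33 splits (largest-remainder per-class
rounding keeps the training prevalence within one patient of the cohort
rate; for 21/71 recurrence this gives a 48/23 split with training
prevalence 14/48 ≈ 0.29). Metrics: accuracy, sensitivity, specificity,
F1 and tie-corrected AUC, positive class = recurrent. Comparators are a
default-hyperparameter random forest (fixed per-iteration seed) and a
diagonal-covariance LDA on the concatenated vectorized image plus
covariates — plain LDA is singular at `p = 1056 + 30 > n` and its
regularization would be arbitrary, so the diagonal variant is the
documented stand-in. A 3-fold CV scheme is available via
`scheme="cv3"`.

## Synthetic cohorts

The generator emulates the statistical structure the classifier
assumes; the emulated study fixes the shape parameters (n = 71,
prevalence 21/71, 1037 features on 33 x 32, 398 genes, 30 DE, q = 30)
while effect sizes are assumptions (documented defaults, three presets:
`null`, moderate default, `strong`).

* The sparse truth is placed on `B_true` (`s_true` cells of magnitude
  `b_scale`); the class-mean shift is derived as
  `Δμ = Σ₁ B_true Σ₂ · noise²` so that `B_true` is exactly the Bayes
  discriminant and support recovery is well defined. Mode covariances
  are AR(1) (ρ₁ = ρ₂ = 0.5 by default).
* Cohort-like mode draws negative-binomial counts
  (gamma–Poisson, dispersion 0.1, baselines log-uniform on [20, 2000],
  log-normal size factors, DE genes shifted by `2^±log2FC`), derives
  covariates as standardized log2-normalized counts of the covariate
  genes, and names features in the `wavelet-XXX_family_stat` dialect.
* RFS is exponential with rate `hazard_base · exp(hazard_beta · z)`
  where `z` is the z-scored true discriminant score (z-scoring keeps
  the baseline rate interpretable across presets); administrative
  censoring at `censor_months = 48` with uniform staggered entry over
  24 months. `hazard_base = 0.02`/month gives roughly 60% event
  probability at the censoring horizon.
* One master seed feeds named `SeedSequence` children per stage
  (structure, labels, covariates, noise, counts, survival), so
  identical seeds give bit-identical cohorts.

What cohort-like data do **not** emulate: scanner heterogeneity and
batch effects, segmentation variability, inter-feature redundancy of
real radiomic panels (features are conditionally independent given the
Kronecker noise), library-preparation artifacts beyond size factors,
and non-exponential hazards. Passing tests therefore demonstrate
correctness and calibration of the estimators under the model's
assumptions, not clinical performance on real cohorts.

## Calibration and problem sizes

The test suite and acceptance script use these study conditions:

* solver oracles on 4x3 and 5x5 random SPD instances (tolerance 1e-6);
* support recovery: 20 seeds, n = 600, 8x8 grid, 5-sparse `B_true`
  (|b| = 0.8), q = 5, sparsity budget 5 — exact-support rate ≥ 0.8;
* α recovery: n = 500, 6x6 grid, q = 4 dense covariate tensor —
  relative Frobenius error < 0.1;
* null calibration: 100 benchmark splits spread over 25 independently
  drawn zero-effect cohorts (4 splits each). A single finite n = 71
  cohort retains chance class separation of order ±0.1 AUC that no
  amount of re-splitting removes, so the calibration averages over
  cohort draws; every method's mean AUC must land in [0.45, 0.55].
  Rank-sum type-I error over 1000 permuted-label draws in [0.03, 0.07];
* signal regime: the `strong` preset (b_scale 1.0, gamma_scale 2.0,
  |log2FC| in [1, 2], hazard_beta 1.0) is calibrated for near-perfect
  Bayes separation; classifier mean AUC over 100 splits must be
  ≥ 0.85, and the log-rank test on the true-score median split must
  reject in ≥ 90% of 20 seeds at n = 200.

## Numerical conventions and edge cases

* Row-major grid fill, zero padding at the tail; the index map records
  the convention so selected pixels are reportable as named features.
* Min-max scaling per feature, fit on training patients only; constant
  features scale to 0; out-of-range test values are clipped to [0, 1].
* Rank-sum test: exact null distribution for tie-free groups of ≤ 8,
  otherwise normal approximation with continuity and tie correction;
  all-identical inputs return p = 1 with a zero-variance flag.
* Median splits send ties to the low group.
* Correlation maps skip constant columns (flagged), BH runs across all
  tested pairs.
* Label dialects {1,2} and {0,1} are auto-detected on input and
  normalized to 1 = recurrent / 2 = non-recurrent, with a log line.

## Known limitations

* Only two-class problems and order-2 tensors are exercised (the
  mode-product and covariance code paths do not hard-wire two modes,
  but higher orders are untested).
* The DE stage is a t-test stand-in, not a dispersion-shrinking NB
  model; with very low counts its ranking will differ from such models.
* CV-based penalty selection refits all moments per fold and is the
  slow path; at the full 33 x 32 scale prefer the sparsity rule unless
  the selected-feature budget is itself in question.
* The diagonal-LDA comparator is a stand-in for unspecified regularized
  LDA variants; its absolute performance should not be over-read.
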