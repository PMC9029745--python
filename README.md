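# radcatch

Covariate-adjusted sparse tensor discriminant analysis for radiomics with
immune gene-expression covariates.

## The problem

In radiogenomic cohorts a patient contributes a high-dimensional radiomic
feature vector computed from CT images (here 1037 named texture/intensity
features), a panel of immune-gene expression counts (398 genes), and a
clinical outcome (cancer recurrence and recurrence-free survival, RFS).
The sample is small (tens of patients), the feature space is huge, and the
gene expression of tumor-infiltrating immune cells partly *drives* the
imaging phenotype — so treating image and expression as independent
predictor blocks both overfits and mis-attributes signal.

`radcatch` implements the covariate-adjusted tensor classification
approach for this setting. The radiomic vector is arranged on a
`p1 x p2` pixel grid (default 33 x 32, leaving 19 zero-padded cells for a
1037-entry vector) so the predictor is a matrix-valued `X`; the selected
differentially expressed genes enter as a covariate vector `U`. The
two-class discriminant score is

```
s(X, U) = a + γᵀ U + ⟨B, X − α ×̄₃ U⟩
```

with

* `γ` — the direct (LDA) effect of expression on recurrence,
  `γ = Ψ⁻¹(φ₁ − φ₂)` from the class means and pooled covariance of `U`;
* `α` — a `p1 x p2 x q` tensor of per-pixel regressions of the image on
  expression; `X_adj = X − α ×̄₃ U` is the *adjusted* image with the
  expression-explained component removed;
* `B` — a sparse discriminant tensor on `X_adj`, estimated under a
  Kronecker-structured (matrix-normal) within-class covariance
  `Σ₂ ⊗ Σ₁` by ℓ1-penalized cyclic coordinate descent,
  `min_B ½⟨B, Σ₁BΣ₂⟩ − ⟨B, D⟩ + λ‖B‖₁` with `D = μ̂₁ − μ̂₂`.

Positive score → predicted recurrent (class 1); posterior
`1/(1+e^{-s})`. Nonzero entries of `B` map back to named radiomic
features through the recorded pixel index map; those adjusted features
then feed rank-sum recurrence contrasts, Kaplan–Meier/log-rank RFS
analysis, and a feature x gene correlation map.

Because matched CT + RNA cohorts are rarely public, the package ships a
first-class synthetic-cohort generator (`radcatch.simulate`) with exactly
the model's statistical structure, in a model-exact mode (for estimator
testing and parameter recovery) and a cohort-like mode (negative-binomial
counts, named wavelet/texture features, censored survival whose hazard
follows the true discriminant score).

## Worked example

```python
import radcatch as rc

# a 71-patient cohort-shaped simulation with strong signal
config = rc.SimConfig.strong(seed=505, exact_prevalence=True)
bundle, truth = rc.generate_cohort_like(config)

report = rc.run_benchmark(
    bundle, iterations=10, seed=506,
    catch_settings=rc.CatchSettings(lambda_rule="sparsity", s_target=10),
)
print(report.table1().to_string(index=False))
```

prints

```
Methods  Accuracy  Sensitivity  Specificity  F1 score  AUC
  catch       1.0          1.0          1.0       1.0  1.0
   dlda       1.0          1.0          1.0       1.0  1.0
     rf       1.0          1.0          1.0       1.0  1.0
```

i.e. on this deliberately strong-signal synthetic cohort every method
separates the classes perfectly on the held-out third of patients
(columns are the mean over the repeated stratified 67/33 splits; the
positive class is recurrence). On the matching zero-effect cohort
(`rc.SimConfig.null(...)`) the same benchmark returns AUC ≈ 0.5 for every
method, which is the calibration property the test suite checks.

The same analysis runs from the shell:

```
radcatch all --simulate -c config.yaml --seed 1 --out results/
```

writing the DE-gene table, fitted model JSON, benchmark metrics table,
coefficient/feature ranking, survival tables and the feature x gene
correlation map into `results/`.

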