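"""Synthetic cohort generator with the discriminant model's structure.

Because the study data (71 stage III colorectal-cancer patients with
1037 radiomic features, 398 immune-gene counts and recurrence-free
survival) are not publicly deposited, this module generates cohorts with
exactly the statistical structure the classifier assumes, in two modes:

* **model-exact** — covariates ``U`` are class-conditionally Gaussian
  (means ``phi_k``, covariance ``Psi = I``) and images ``X`` are
  matrix-normal around ``mu_k + alpha xbar_3 U`` with AR(1) mode
  covariances.  Estimator unit tests and parameter-recovery studies use
  this mode because the generating law matches the fitted model exactly.
* **cohort-like** — adds negative-binomial gene counts (with a chosen set
  of differentially expressed genes), derives covariates as standardized
  log2-normalized counts of those genes, names the 1037 radiomic features
  in the wavelet/texture dialect, and draws right-censored
  recurrence-free-survival times whose exponential hazard follows the
  true discriminant score.

All randomness flows from one master seed through named
``numpy.random.SeedSequence`` children, so every sub-stage is
reproducible in isolation and identical seeds give bit-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import CohortBundle
from .tensorize import FeatureIndexMap, FeatureImageStack, image_to_vector

__all__ = [
    "SimConfigError",
    "SimConfig",
    "SimTruth",
    "ar1_covariance",
    "make_feature_names",
    "make_gene_names",
    "generate_model_exact",
    "generate_cohort_like",
    "write_cohort",
]

RECURRENT, NON_RECURRENT = 1, 2

# wavelet decomposition channels and per-family statistic pools used to name
# synthetic radiomic features ("wavelet-LHH_glcm_Idmn", ...)
_CHANNELS = ("LLL", "LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH")
_FAMILY_STATS = {
    "glcm": (
        "Autocorrelation", "ClusterProminence", "ClusterShade", "ClusterTendency",
        "Contrast", "Correlation", "DifferenceAverage", "DifferenceEntropy",
        "DifferenceVariance", "Id", "Idm", "Idmn", "Idn", "Imc1", "Imc2",
        "InverseVariance", "JointAverage", "JointEnergy", "JointEntropy", "MCC",
        "MaximumProbability", "SumAverage", "SumEntropy", "SumSquares",
    ),
    "glrlm": (
        "GrayLevelNonUniformity", "GrayLevelNonUniformityNormalized",
        "GrayLevelVariance", "HighGrayLevelRunEmphasis", "LongRunEmphasis",
        "LongRunHighGrayLevelEmphasis", "LongRunLowGrayLevelEmphasis",
        "LowGrayLevelRunEmphasis", "RunEntropy", "RunLengthNonUniformity",
        "RunLengthNonUniformityNormalized", "RunPercentage", "RunVariance",
        "ShortRunEmphasis", "ShortRunHighGrayLevelEmphasis",
        "ShortRunLowGrayLevelRunEmphasis",
    ),
    "glszm": (
        "GrayLevelNonUniformity", "GrayLevelNonUniformityNormalized",
        "GrayLevelVariance", "HighGrayLevelZoneEmphasis", "LargeAreaEmphasis",
        "LargeAreaHighGrayLevelEmphasis", "LargeAreaLowGrayLevelEmphasis",
        "LowGrayLevelZoneEmphasis", "SizeZoneNonUniformity",
        "SizeZoneNonUniformityNormalized", "SmallAreaEmphasis",
        "SmallAreaHighGrayLevelEmphasis", "SmallAreaLowGrayLevelEmphasis",
        "ZoneEntropy", "ZonePercentage", "ZoneVariance",
    ),
    "gldm": (
        "DependenceEntropy", "DependenceNonUniformity",
        "DependenceNonUniformityNormalized", "DependenceVariance",
        "GrayLevelNonUniformity", "GrayLevelVariance", "HighGrayLevelEmphasis",
        "LargeDependenceEmphasis", "LargeDependenceHighGrayLevelEmphasis",
        "LargeDependenceLowGrayLevelEmphasis", "LowGrayLevelEmphasis",
        "SmallDependenceEmphasis", "SmallDependenceHighGrayLevelEmphasis",
        "SmallDependenceLowGrayLevelEmphasis",
    ),
    "ngtdm": ("Busyness", "Coarseness", "Complexity", "Contrast", "Strength"),
    "firstorder": (
        "Energy", "Entropy", "InterquartileRange", "Kurtosis", "Maximum",
        "MeanAbsoluteDeviation", "Mean", "Median", "Minimum", "Percentile10",
        "Percentile90", "Range", "RobustMeanAbsoluteDeviation",
        "RootMeanSquared", "Skewness", "TotalEnergy", "Uniformity", "Variance",
    ),
}

_IMMUNE_SYMBOLS = (
    "PECAM1", "PRDM1", "AIF1", "IL10", "ISG20", "TLR8", "SNAI2", "CD274",
    "CTLA4", "FOXP3", "GZMB", "IFNG", "IL6", "CXCL9", "CXCL10", "CCL5",
    "TGFB1", "TNF", "LAG3", "HAVCR2", "CD8A", "CD4", "MS4A1", "NKG7",
    "STAT1", "IRF1", "IDO1", "TLR4", "TLR7", "CD68",
)


class SimConfigError(ValueError):
    pass


def make_feature_names(n_features: int) -> tuple[str, ...]:
    """Deterministic unique radiomic-style names: ``wavelet-XXX_family_stat``."""
    names: list[str] = []
    for channel in _CHANNELS:
        for family, stats in _FAMILY_STATS.items():
            for stat in stats:
                names.append(f"wavelet-{channel}_{family}_{stat}")
    k = 0
    while len(names) < n_features:
        channel = _CHANNELS[k % len(_CHANNELS)]
        names.append(f"wavelet-{channel}_firstorder_Moment{k // len(_CHANNELS) + 3}")
        k += 1
    return tuple(names[:n_features])


def make_gene_names(g_total: int) -> tuple[str, ...]:
    names = list(_IMMUNE_SYMBOLS[:g_total])
    names += [f"IMMG{k:04d}" for k in range(1, g_total - len(names) + 1)]
    return tuple(names[:g_total])


def ar1_covariance(p: int, rho: float) -> np.ndarray:
    """Unit-diagonal AR(1) correlation matrix, rho^|i-j| (positive definite)."""
    if not -1.0 < rho < 1.0:
        raise SimConfigError(f"AR(1) parameter must be in (-1, 1), got {rho}")
    idx = np.arange(p)
    return rho ** np.abs(idx[:, None] - idx[None, :])


@dataclass
class SimConfig:
    """Generating parameters for one synthetic cohort.

    Defaults mirror the emulated study: 71 patients with a 21/71
    recurrence prevalence, 1037 radiomic features on a 33 x 32 grid,
    398 immune genes with 30 differentially expressed, and covariates
    taken from 30 genes.  Effect sizes (``b_scale``, ``alpha_scale``,
    ``gamma_scale``, ``log2fc_range``, ``hazard_beta``) are assumptions,
    not estimates — the study never reports them — and default to a
    moderate-signal regime; see the presets for null and strong regimes.
    """

    n: int = 71
    p1: int = 33
    p2: int = 32
    n_features: int = 1037
    q: int = 30
    g_total: int = 398
    g_de: int = 30
    prevalence: float = 21 / 71
    exact_prevalence: bool = False
    # discriminant-tensor truth: s_true cells of magnitude b_scale
    s_true: int = 10
    b_scale: float = 0.5
    mu_shift: np.ndarray | None = None
    # covariate-to-image links: alpha_links random (pixel, gene) entries
    alpha_true: np.ndarray | None = None
    alpha_scale: float = 0.3
    alpha_links: int = 20
    gamma_scale: float = 1.0
    rho1: float = 0.5
    rho2: float = 0.5
    noise_scale: float = 1.0
    # count model
    log2fc_range: tuple[float, float] = (0.5, 1.5)
    dispersion: float = 0.1
    base_mean_range: tuple[float, float] = (20.0, 2000.0)
    size_factor_sd: float = 0.15
    # survival model
    hazard_base: float = 0.02
    hazard_beta: float = 0.5
    censor_months: float = 48.0
    accrual_months: float = 24.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 4:
            raise SimConfigError("n must be >= 4")
        if self.p1 < 1 or self.p2 < 1:
            raise SimConfigError("grid dimensions must be >= 1")
        if not 0.0 < self.prevalence < 1.0:
            raise SimConfigError("prevalence must be in (0, 1)")
        if self.g_de > self.g_total:
            raise SimConfigError("g_de cannot exceed g_total")
        if self.q > self.g_total:
            raise SimConfigError("q cannot exceed g_total")
        if self.n_features > self.p1 * self.p2:
            raise SimConfigError(
                f"{self.n_features} features do not fit a {self.p1}x{self.p2} grid"
            )
        if self.s_true > self.n_features:
            raise SimConfigError("s_true exceeds the feature count")
        # AR(1) validity doubles as the positive-definiteness check
        ar1_covariance(2, self.rho1)
        ar1_covariance(2, self.rho2)
        if self.noise_scale <= 0:
            raise SimConfigError("noise_scale must be positive")

    @classmethod
    def null(cls, **overrides) -> "SimConfig":
        """Zero-effect cohort: no class signal anywhere, no hazard link."""
        base = dict(
            s_true=0, b_scale=0.0, alpha_scale=0.0, alpha_links=0,
            gamma_scale=0.0, g_de=0, hazard_beta=0.0,
        )
        base.update(overrides)
        return cls(**base)

    @classmethod
    def strong(cls, **overrides) -> "SimConfig":
        """Calibrated strong-signal regime (near-perfect Bayes separation)."""
        base = dict(
            s_true=10, b_scale=1.0, alpha_scale=0.3, alpha_links=20,
            gamma_scale=2.0, log2fc_range=(1.0, 2.0), hazard_beta=1.0,
        )
        base.update(overrides)
        return cls(**base)


@dataclass
class SimTruth:
    """Generating parameters and latent variables, kept for recovery tests."""

    B_true: np.ndarray
    alpha_true: np.ndarray
    gamma_true: np.ndarray
    phi1: np.ndarray
    phi2: np.ndarray
    mu1: np.ndarray
    mu2: np.ndarray
    sigma1: np.ndarray
    sigma2: np.ndarray
    intercept_true: float
    labels: np.ndarray
    U: np.ndarray
    scores: np.ndarray
    de_gene_ids: tuple[str, ...]
    de_log2fc: dict
    config: dict = field(default_factory=dict)

    def support(self) -> set[tuple[int, int]]:
        return {(int(i), int(j)) for i, j in np.argwhere(self.B_true != 0.0)}

    def recompute_scores(self) -> np.ndarray:
        """Scores re-derived from stored parameters and latent data."""
        q = self.gamma_true.size
        lin = self.intercept_true + np.zeros(len(self.labels))
        if q:
            lin = lin + self.U @ self.gamma_true
        # X_adj contribution: stored scores already folded in <B, X_adj>;
        # recomputation needs X, so callers pass it through score_patients.
        return lin

    def score_patients(self, X: np.ndarray) -> np.ndarray:
        """True discriminant score for an image stack drawn from this truth."""
        X_adj = X
        if self.gamma_true.size:
            X_adj = X - np.einsum("ijl,nl->nij", self.alpha_true, self.U)
        lin = np.tensordot(X_adj, self.B_true, axes=([1, 2], [0, 1]))
        if self.gamma_true.size:
            lin = lin + self.U @ self.gamma_true
        return self.intercept_true + lin

    def to_json(self, path: str | Path | None = None) -> str:
        def arr(a):
            a = np.asarray(a, dtype=float)
            return {"shape": list(a.shape), "data": a.ravel().tolist()}

        payload = {
            "B_true": arr(self.B_true),
            "alpha_true": arr(self.alpha_true),
            "gamma_true": arr(self.gamma_true),
            "phi1": arr(self.phi1),
            "phi2": arr(self.phi2),
            "mu1": arr(self.mu1),
            "mu2": arr(self.mu2),
            "sigma1": arr(self.sigma1),
            "sigma2": arr(self.sigma2),
            "intercept_true": self.intercept_true,
            "labels": self.labels.tolist(),
            "U": arr(self.U),
            "scores": self.scores.tolist(),
            "de_gene_ids": list(self.de_gene_ids),
            "de_log2fc": self.de_log2fc,
            "config": self.config,
        }
        text = json.dumps(payload)
        if path is not None:
            Path(path).write_text(text)
        return text


def _child_rngs(seed: int, names: tuple[str, ...]) -> dict:
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {name: np.random.default_rng(child) for name, child in zip(names, children)}


_STAGES = ("structure", "labels", "covariates", "noise", "counts", "survival")


def _draw_labels(config: SimConfig, rng) -> np.ndarray:
    if config.exact_prevalence:
        n_rec = int(round(config.n * config.prevalence))
        labels = np.full(config.n, NON_RECURRENT)
        labels[:n_rec] = RECURRENT
        return rng.permutation(labels)
    return np.where(rng.random(config.n) < config.prevalence, RECURRENT, NON_RECURRENT)


def _structure(config: SimConfig, rng):
    """True B, alpha, gamma direction, and the implied class-mean shift."""
    p1, p2, q = config.p1, config.p2, config.q
    S1 = ar1_covariance(p1, config.rho1)
    S2 = ar1_covariance(p2, config.rho2)
    occupied = np.arange(config.n_features)  # pads excluded from any truth

    if config.mu_shift is not None:
        mu_shift = np.asarray(config.mu_shift, dtype=float)
        if mu_shift.shape != (p1, p2):
            raise SimConfigError("mu_shift shape must be (p1, p2)")
        cov = config.noise_scale**2
        B_true = np.linalg.solve(S1, mu_shift) @ np.linalg.inv(S2) / cov
    else:
        B_true = np.zeros((p1, p2))
        if config.s_true > 0 and config.b_scale != 0.0:
            cells = rng.choice(occupied, size=config.s_true, replace=False)
            signs = rng.choice([-1.0, 1.0], size=config.s_true)
            B_true.ravel()[cells] = signs * config.b_scale
        # mean shift implied by the discriminant: Delta-mu = cov * S1 B S2
        mu_shift = config.noise_scale**2 * (S1 @ B_true @ S2)
        pad_mask = np.zeros(p1 * p2, dtype=bool)
        pad_mask[config.n_features :] = True
        mu_shift.ravel()[pad_mask] = 0.0  # pads always carry exactly 0

    if config.alpha_true is not None:
        alpha = np.asarray(config.alpha_true, dtype=float)
        if alpha.shape != (p1, p2, q):
            raise SimConfigError("alpha_true shape must be (p1, p2, q)")
    else:
        alpha = np.zeros((p1, p2, q))
        if q > 0 and config.alpha_links > 0 and config.alpha_scale != 0.0:
            flat_cells = rng.choice(occupied, size=config.alpha_links, replace=True)
            genes = rng.integers(0, q, size=config.alpha_links)
            vals = config.alpha_scale * rng.choice([-1.0, 1.0], size=config.alpha_links)
            for cell, gene, val in zip(flat_cells, genes, vals):
                alpha[cell // p2, cell % p2, gene] += val

    phi2 = np.zeros(q)
    phi1 = np.zeros(q)
    if q > 0 and config.gamma_scale != 0.0:
        k = min(q, 5)
        direction = np.zeros(q)
        direction[:k] = 1.0 / np.sqrt(k)
        phi1 = config.gamma_scale * direction
    return S1, S2, B_true, alpha, mu_shift, phi1, phi2


def _tensor_noise(rng, n, S1, S2, scale):
    L1 = np.linalg.cholesky(S1)
    L2 = np.linalg.cholesky(S2)
    Z = rng.standard_normal((n, S1.shape[0], S2.shape[0]))
    return scale * np.einsum("ij,njk,lk->nil", L1, Z, L2)


def _zero_pads(X: np.ndarray, config: SimConfig) -> np.ndarray:
    flat = X.reshape(X.shape[0], -1)
    flat[:, config.n_features :] = 0.0
    return flat.reshape(X.shape)


def _survival(config: SimConfig, scores: np.ndarray, rng):
    """Exponential RFS times whose log-hazard follows the z-scored score."""
    sd = scores.std()
    z = (scores - scores.mean()) / sd if sd > 0 else np.zeros_like(scores)
    rate = config.hazard_base * np.exp(config.hazard_beta * z)
    T = rng.exponential(1.0 / rate)
    censor = config.censor_months - rng.uniform(0.0, config.accrual_months, size=len(T))
    censor = np.maximum(censor, 1e-6)
    event = (T <= censor).astype(int)
    time = np.minimum(T, censor)
    return time, event


def _truth_and_bundle(config, labels, U, X, names, counts, gene_names, de_ids,
                      de_fc, S1, S2, mu_shift, phi1, phi2, B_true, alpha, rngs):
    q = config.q
    gamma_true = phi1 - phi2  # Psi = I in the generating law
    pi1 = config.prevalence
    intercept_true = float(
        np.log(pi1 / (1 - pi1))
        - 0.5 * np.sum(B_true * mu_shift)
        - (0.5 * gamma_true @ (phi1 + phi2) if q else 0.0)
    )
    truth = SimTruth(
        B_true=B_true,
        alpha_true=alpha,
        gamma_true=gamma_true,
        phi1=phi1,
        phi2=phi2,
        mu1=mu_shift,
        mu2=np.zeros_like(mu_shift),
        sigma1=S1,
        sigma2=S2,
        intercept_true=intercept_true,
        labels=labels,
        U=U,
        scores=np.zeros(config.n),
        de_gene_ids=tuple(de_ids),
        de_log2fc={g: float(f) for g, f in de_fc.items()},
        config={k: v for k, v in asdict(config).items()
                if not isinstance(v, np.ndarray)},
    )
    truth.scores = truth.score_patients(X)

    index_map = FeatureIndexMap(names, config.p1, config.p2)
    radiomics = pd.DataFrame(
        [image_to_vector(img, index_map) for img in X],
        index=pd.Index([f"P{k:04d}" for k in range(1, config.n + 1)],
                       name="patient_id"),
        columns=list(names),
    )
    time, event = _survival(config, truth.scores, rngs["survival"])
    clinical = pd.DataFrame(
        {"recurrence": labels, "rfs_months": time, "event": event},
        index=radiomics.index,
    )
    counts_frame = None
    if counts is not None:
        counts_frame = pd.DataFrame(counts, index=radiomics.index,
                                    columns=list(gene_names))
    bundle = CohortBundle(
        radiomics=radiomics,
        counts=counts_frame,
        clinical=clinical,
        provenance={"generator": "radcatch.simulate", "seed": config.seed,
                    "mode": "cohort-like" if counts is not None else "model-exact"},
    )
    return bundle, truth


def generate_model_exact(config: SimConfig) -> tuple[CohortBundle, SimTruth]:
    """Cohort drawn exactly from the classifier's generative model.

    ``U | Y=k ~ N(phi_k, I)`` and ``X | U, Y=k`` is matrix-normal around
    ``mu_k + alpha xbar_3 U`` with AR(1) mode covariances.  The returned
    bundle has no count table (covariates are emitted through the truth
    object); labels are coded 1 = recurrent, 2 = non-recurrent.
    """
    rngs = _child_rngs(config.seed, _STAGES)
    S1, S2, B_true, alpha, mu_shift, phi1, phi2 = _structure(config, rngs["structure"])
    labels = _draw_labels(config, rngs["labels"])
    rec = labels == RECURRENT

    U = rngs["covariates"].standard_normal((config.n, config.q))
    if config.q:
        U[rec] += phi1
        U[~rec] += phi2
    X = _tensor_noise(rngs["noise"], config.n, S1, S2, config.noise_scale)
    X[rec] += mu_shift
    if config.q:
        X += np.einsum("ijl,nl->nij", alpha, U)
    X = _zero_pads(X, config)

    names = make_feature_names(config.n_features)
    return _truth_and_bundle(config, labels, U, X, names, None, (), (), {},
                             S1, S2, mu_shift, phi1, phi2, B_true, alpha, rngs)


def generate_cohort_like(config: SimConfig) -> tuple[CohortBundle, SimTruth]:
    """Cohort with gene counts, named features and censored survival.

    Counts are negative-binomial around ``size_factor x baseline x
    2^(log2fc * 1[recurrent])`` for the differentially expressed genes;
    covariates are the standardized log2-normalized counts of the first
    ``q`` covariate genes (the DE set when ``g_de > 0``); images follow
    the model-exact law given those covariates; RFS is exponential with
    log-hazard proportional to the true discriminant score.
    """
    rngs = _child_rngs(config.seed, _STAGES)
    S1, S2, B_true, alpha, mu_shift, phi1, phi2 = _structure(config, rngs["structure"])
    labels = _draw_labels(config, rngs["labels"])
    rec = labels == RECURRENT

    gene_names = make_gene_names(config.g_total)
    crng = rngs["counts"]
    base = np.exp(crng.uniform(np.log(config.base_mean_range[0]),
                               np.log(config.base_mean_range[1]),
                               size=config.g_total))
    size_factors = np.exp(crng.normal(0.0, config.size_factor_sd, size=config.n))
    de_idx = crng.choice(config.g_total, size=config.g_de, replace=False)
    lo, hi = config.log2fc_range
    de_fc_vals = crng.uniform(lo, hi, size=config.g_de) * crng.choice(
        [-1.0, 1.0], size=config.g_de
    )
    log2fc = np.zeros(config.g_total)
    log2fc[de_idx] = de_fc_vals
    mean = size_factors[:, None] * base[None, :]
    mean = mean * np.where(rec[:, None], 2.0 ** log2fc[None, :], 1.0)
    if config.dispersion > 0:
        shape = 1.0 / config.dispersion
        lam = crng.gamma(shape, mean * config.dispersion)
    else:
        lam = mean
    counts = crng.poisson(lam).astype(np.int64)

    # covariates: standardized log2-normalized counts of the covariate genes
    if config.q:
        cov_idx = de_idx[: config.q] if config.g_de else np.arange(config.q)
        if len(cov_idx) < config.q:
            extra = np.setdiff1d(np.arange(config.g_total), cov_idx)[: config.q - len(cov_idx)]
            cov_idx = np.concatenate([cov_idx, extra])
        expr = np.log2(counts[:, cov_idx] / size_factors[:, None] + 1.0)
        sd = expr.std(axis=0)
        sd[sd == 0] = 1.0
        U = (expr - expr.mean(axis=0)) / sd
    else:
        U = np.zeros((config.n, 0))

    X = _tensor_noise(rngs["noise"], config.n, S1, S2, config.noise_scale)
    X[rec] += mu_shift
    if config.q:
        X += np.einsum("ijl,nl->nij", alpha, U)
    X = _zero_pads(X, config)

    # the generating class separation of U is empirical here (counts break
    # exact Gaussianity): record plug-in phi_k so truth scores stay exact
    if config.q:
        phi1 = U[rec].mean(axis=0) if rec.any() else np.zeros(config.q)
        phi2 = U[~rec].mean(axis=0) if (~rec).any() else np.zeros(config.q)

    names = make_feature_names(config.n_features)
    de_ids = tuple(gene_names[i] for i in de_idx)
    de_fc = {gene_names[i]: log2fc[i] for i in de_idx}
    return _truth_and_bundle(config, labels, U, X, names, counts, gene_names,
                             de_ids, de_fc, S1, S2, mu_shift, phi1, phi2,
                             B_true, alpha, rngs)


def write_cohort(
    bundle: CohortBundle,
    truth: SimTruth | None,
    outdir: str | Path,
    delimiter: str = ",",
) -> dict:
    """Emit the three cohort files (and truth JSON) for interface_io."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    ext = "tsv" if delimiter == "\t" else "csv"
    paths["radiomics"] = outdir / f"radiomics.{ext}"
    bundle.radiomics.to_csv(paths["radiomics"], sep=delimiter)
    if bundle.counts is not None:
        paths["counts"] = outdir / f"counts.{ext}"
        bundle.counts.to_csv(paths["counts"], sep=delimiter)
    paths["clinical"] = outdir / f"clinical.{ext}"
    bundle.clinical.to_csv(paths["clinical"], sep=delimiter)
    if truth is not None:
        paths["truth"] = outdir / "truth.json"
        truth.to_json(paths["truth"])
    return paths
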