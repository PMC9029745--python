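"""Covariate-adjusted sparse tensor discriminant analysis.

The classifier combines three effects for a two-class problem
(1 = recurrent, 2 = non-recurrent):

* ``gamma`` — the direct effect of the gene-expression covariates ``U`` on
  the class, estimated as a plug-in LDA direction ``Psi^{-1}(phi_1 - phi_2)``
  from the class means ``phi_k`` and pooled covariance ``Psi`` of ``U``;
* ``alpha`` — the covariate-to-image effect, a ``p1 x p2 x q`` tensor of
  per-pixel OLS coefficients of within-class-centered images on
  within-class-centered covariates.  ``X_adj = X - alpha xbar_3 U`` is the
  image with the expression-explained component removed;
* ``B`` — a sparse discriminant tensor on the adjusted image, assuming a
  Kronecker-structured (matrix-normal) within-class covariance
  ``Sigma_2 (x) Sigma_1`` estimated by flip-flop moment iteration.  ``B``
  solves an l1-penalized quadratic program by cyclic coordinate descent
  with warm starts along a log-spaced penalty path.

The decision score is ``s = a + gamma' U + <B, X_adj>`` with the standard
LDA-composition intercept ``a``; ``s > 0`` predicts recurrence and the
posterior is ``1 / (1 + exp(-s))``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from ._solver import cd_solve, lambda_path, penalized_objective
from .tensorize import FeatureIndexMap

__all__ = [
    "CatchError",
    "CatchNumericalError",
    "CatchSettings",
    "CatchModel",
    "estimate_alpha",
    "adjust_tensor",
    "estimate_mode_covariances",
    "fit_B",
    "fit_catch",
    "predict",
    "rank_selected_features",
]

RECURRENT, NON_RECURRENT = 1, 2


class CatchError(ValueError):
    pass


class CatchNumericalError(RuntimeError):
    pass


@dataclass
class CatchSettings:
    """Estimation knobs; defaults are the package-wide conventions.

    lambda_rule: "cv" (5-fold stratified CV maximizing AUC, ties to the
    larger penalty), "sparsity" (smallest path penalty keeping at most
    ``s_target`` nonzeros, mirroring a fixed selected-feature budget), or
    "fixed" (use ``fixed_lambda``).
    """

    lambda_rule: str = "cv"
    n_lambdas: int = 50
    lambda_min_ratio: float = 0.01
    s_target: int = 10
    cv_folds: int = 5
    cv_seed: int = 0
    fixed_lambda: float | None = None
    ridge_eps: float = 1e-4
    alpha_ridge: float = 0.0
    cd_tol: float = 1e-8
    cd_max_sweeps: int | None = None
    flipflop_tol: float = 1e-6
    flipflop_max_iter: int = 100

    def __post_init__(self) -> None:
        if self.lambda_rule not in ("cv", "sparsity", "fixed"):
            raise CatchError(f"unknown lambda rule {self.lambda_rule!r}")
        if self.lambda_rule == "fixed" and self.fixed_lambda is None:
            raise CatchError("lambda_rule='fixed' requires fixed_lambda")


def _class_masks(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels)
    rec = labels == RECURRENT
    non = labels == NON_RECURRENT
    if rec.sum() + non.sum() != labels.size:
        raise CatchError("labels must be coded 1 (recurrent) / 2 (non-recurrent)")
    return rec, non


def estimate_alpha(
    X: np.ndarray,
    U: np.ndarray,
    labels,
    ridge: float = 0.0,
) -> np.ndarray:
    """Entrywise OLS of within-class-centered X on within-class-centered U.

    Returns the ``p1 x p2 x q`` covariate-effect tensor; ``alpha[i, j, :]``
    is the coefficient vector of pixel (i, j).
    """
    X = np.asarray(X, dtype=float)
    U = np.asarray(U, dtype=float)
    n, p1, p2 = X.shape
    q = U.shape[1]
    if U.shape[0] != n:
        raise CatchError("X and U disagree on patient count")
    if n <= q:
        raise CatchError("need n > q covariates for the OLS step")
    rec, non = _class_masks(labels)
    Xc = X.copy()
    Uc = U.copy()
    for mask in (rec, non):
        if mask.any():
            Xc[mask] -= X[mask].mean(axis=0)
            Uc[mask] -= U[mask].mean(axis=0)
    gram = Uc.T @ Uc
    if ridge > 0.0:
        gram = gram + ridge * np.mean(np.diag(gram)) * np.eye(q)
    elif np.linalg.matrix_rank(gram) < q:
        raise CatchError(
            "centered covariates are rank deficient; pass a ridge epsilon "
            "(e.g. ridge=1e-4)"
        )
    coef = np.linalg.solve(gram, Uc.T @ Xc.reshape(n, -1))  # (q, p1*p2)
    return coef.T.reshape(p1, p2, q)


def adjust_tensor(X: np.ndarray, U: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """``X_adj = X - alpha xbar_3 U``: remove the covariate-explained image."""
    X = np.asarray(X, dtype=float)
    if alpha is None or alpha.size == 0 or (U is not None and np.size(U) == 0):
        return X.copy()
    U = np.asarray(U, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    if alpha.shape[:2] != X.shape[1:] or alpha.shape[2] != U.shape[1]:
        raise CatchError(
            f"shape mismatch: X {X.shape}, U {U.shape}, alpha {alpha.shape}"
        )
    if U.shape[0] != X.shape[0]:
        raise CatchError("X and U disagree on patient count")
    return X - np.einsum("ijl,nl->nij", alpha, U)


@dataclass
class ModeCovariances:
    """Flip-flop Kronecker covariance estimate with Sigma1[0,0] = 1."""

    sigma1: np.ndarray
    sigma2: np.ndarray
    n_iter: int
    converged: bool
    ridge_applied: bool

    def __iter__(self):
        return iter((self.sigma1, self.sigma2))


def _ensure_pd(S: np.ndarray, ridge_eps: float) -> tuple[np.ndarray, bool]:
    S = 0.5 * (S + S.T)
    eigmin = np.linalg.eigvalsh(S)[0]
    if eigmin < 1e-8:
        S = S + ridge_eps * np.mean(np.diag(S)) * np.eye(S.shape[0])
        return S, True
    return S, False


def estimate_mode_covariances(
    X_adj: np.ndarray,
    labels,
    ridge_eps: float = 1e-4,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> ModeCovariances:
    """Flip-flop moment estimation of the two mode covariances.

    Alternates ``Sigma1 <- (1/(n p2)) sum_i E_i Sigma2^{-1} E_i'`` and
    ``Sigma2 <- (1/(n p1)) sum_i E_i' Sigma1^{-1} E_i`` on within-class
    residuals, from identity starts, until the relative Frobenius change
    drops below ``tol`` (at most ``max_iter`` rounds), then rescales so
    ``Sigma1[0, 0] = 1`` (scale absorbed into ``Sigma2``).  A ridge of
    ``ridge_eps * mean(diag)`` is added whenever an iterate is near
    singular.
    """
    X_adj = np.asarray(X_adj, dtype=float)
    n, p1, p2 = X_adj.shape
    if n < 3:
        raise CatchError("mode covariance estimation needs n >= 3")
    rec, non = _class_masks(labels)
    E = X_adj.copy()
    for mask in (rec, non):
        if mask.any():
            E[mask] -= X_adj[mask].mean(axis=0)
    S1 = np.eye(p1)
    S2 = np.eye(p2)
    ridge_used = False
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        S1_prev, S2_prev = S1, S2
        S2_pd, r2 = _ensure_pd(S2, ridge_eps)
        M = E @ np.linalg.inv(S2_pd)
        S1 = np.einsum("nij,nkj->ik", M, E) / (n * p2)
        S1, r1 = _ensure_pd(S1, ridge_eps)
        Minv = np.linalg.inv(S1)
        S2 = np.einsum("nji,njk->ik", E, np.einsum("ij,njk->nik", Minv, E)) / (n * p1)
        S2, r3 = _ensure_pd(S2, ridge_eps)
        ridge_used = ridge_used or r1 or r2 or r3
        if not (np.all(np.isfinite(S1)) and np.all(np.isfinite(S2))):
            raise CatchNumericalError(
                "flip-flop iteration diverged; increase ridge_eps"
            )
        rel = max(
            np.linalg.norm(S1 - S1_prev) / max(np.linalg.norm(S1_prev), 1e-300),
            np.linalg.norm(S2 - S2_prev) / max(np.linalg.norm(S2_prev), 1e-300),
        )
        if rel < tol:
            converged = True
            break
    scale = S1[0, 0]
    S1 = S1 / scale
    S2 = S2 * scale
    return ModeCovariances(S1, S2, it, converged, ridge_used)


def _mean_difference(X_adj: np.ndarray, labels) -> np.ndarray:
    rec, non = _class_masks(labels)
    if not rec.any() or not non.any():
        raise CatchError("both classes required")
    return X_adj[rec].mean(axis=0) - X_adj[non].mean(axis=0)


def fit_B(
    X_adj: np.ndarray,
    labels,
    sigma1: np.ndarray,
    sigma2: np.ndarray,
    lam: float,
    B0: np.ndarray | None = None,
    tol: float = 1e-8,
    max_sweeps: int | None = None,
) -> np.ndarray:
    """Sparse discriminant tensor at a single penalty value.

    Minimizes ``0.5 <B, Sigma1 B Sigma2> - <B, D> + lam ||B||_1`` with
    ``D`` the adjusted-image class-mean difference (recurrent minus
    non-recurrent).  ``lam >= max|D|`` yields ``B = 0`` exactly.
    """
    D = _mean_difference(np.asarray(X_adj, dtype=float), labels)
    B, info = cd_solve(D, sigma1, sigma2, lam, B0=B0, tol=tol, max_sweeps=max_sweeps)
    if not info["converged"]:
        warnings.warn(
            "coordinate descent hit the sweep budget before converging; "
            "returning the last iterate",
            RuntimeWarning,
        )
    return B


@dataclass
class CatchModel:
    """Fitted covariate-adjusted tensor discriminant model."""

    alpha: np.ndarray
    gamma: np.ndarray
    B: np.ndarray
    intercept: float
    pi1: float
    pi2: float
    phi1: np.ndarray
    phi2: np.ndarray
    psi: np.ndarray
    mu1: np.ndarray
    mu2: np.ndarray
    sigma1: np.ndarray
    sigma2: np.ndarray
    lam: float
    index_map: FeatureIndexMap | None = None
    settings: CatchSettings = field(default_factory=CatchSettings)
    converged: bool = True
    cv_auc: float | None = None
    fitted: bool = True

    @property
    def q(self) -> int:
        return int(self.gamma.size)

    def n_selected(self) -> int:
        return int(np.count_nonzero(self.B))

    def predict(self, X, U=None):
        return predict(self, X, U)

    def to_json(self, path: str | Path | None = None) -> str:
        def arr(a):
            a = np.asarray(a, dtype=float)
            return {"shape": list(a.shape), "data": a.ravel().tolist()}

        payload = {
            "alpha": arr(self.alpha),
            "gamma": arr(self.gamma),
            "B": arr(self.B),
            "intercept": self.intercept,
            "pi1": self.pi1,
            "pi2": self.pi2,
            "phi1": arr(self.phi1),
            "phi2": arr(self.phi2),
            "psi": arr(self.psi),
            "mu1": arr(self.mu1),
            "mu2": arr(self.mu2),
            "sigma1": arr(self.sigma1),
            "sigma2": arr(self.sigma2),
            "lambda": self.lam,
            "converged": self.converged,
            "cv_auc": self.cv_auc,
            "settings": asdict(self.settings),
            "index_map": json.loads(self.index_map.to_json())
            if self.index_map is not None
            else None,
        }
        text = json.dumps(payload)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "CatchModel":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        obj = json.loads(text)

        def arr(d):
            return np.asarray(d["data"], dtype=float).reshape(d["shape"])

        index_map = None
        if obj["index_map"] is not None:
            m = obj["index_map"]
            names = tuple(r["feature"] for r in m["features"])
            index_map = FeatureIndexMap(names, m["p1"], m["p2"], m["fill_order"], m["pad_value"])
        return cls(
            alpha=arr(obj["alpha"]),
            gamma=arr(obj["gamma"]),
            B=arr(obj["B"]),
            intercept=obj["intercept"],
            pi1=obj["pi1"],
            pi2=obj["pi2"],
            phi1=arr(obj["phi1"]),
            phi2=arr(obj["phi2"]),
            psi=arr(obj["psi"]),
            mu1=arr(obj["mu1"]),
            mu2=arr(obj["mu2"]),
            sigma1=arr(obj["sigma1"]),
            sigma2=arr(obj["sigma2"]),
            lam=obj["lambda"],
            settings=CatchSettings(**obj["settings"]),
            converged=obj["converged"],
            cv_auc=obj["cv_auc"],
            index_map=index_map,
        )


def _solve_down_path(D, S1, S2, lams, tol, max_sweeps):
    """Warm-started solutions for each penalty, largest first."""
    out = []
    B = np.zeros_like(D)
    for lam in lams:
        B, info = cd_solve(D, S1, S2, lam, B0=B, tol=tol, max_sweeps=max_sweeps)
        out.append((float(lam), B.copy(), info["converged"]))
    return out


def _gamma_from_moments(U, labels, ridge_eps):
    rec, non = _class_masks(labels)
    phi1 = U[rec].mean(axis=0)
    phi2 = U[non].mean(axis=0)
    n1, n2 = rec.sum(), non.sum()
    S_rec = np.cov(U[rec], rowvar=False, ddof=1)
    S_non = np.cov(U[non], rowvar=False, ddof=1)
    psi = ((n1 - 1) * np.atleast_2d(S_rec) + (n2 - 1) * np.atleast_2d(S_non)) / (
        n1 + n2 - 2
    )
    psi, _ = _ensure_pd(psi, ridge_eps)
    gamma = np.linalg.solve(psi, phi1 - phi2)
    return gamma, phi1, phi2, psi


def _fit_core(X, U, labels, settings):
    """Moments, alpha/gamma, covariances and the penalty path pieces."""
    q = 0 if U is None else U.shape[1]
    if q > 0:
        alpha = estimate_alpha(X, U, labels, ridge=settings.alpha_ridge)
        X_adj = adjust_tensor(X, U, alpha)
        gamma, phi1, phi2, psi = _gamma_from_moments(U, labels, settings.ridge_eps)
    else:
        alpha = np.zeros(X.shape[1:] + (0,))
        X_adj = X.copy()
        gamma = np.zeros(0)
        phi1 = phi2 = np.zeros(0)
        psi = np.zeros((0, 0))
    rec, non = _class_masks(labels)
    mu1 = X_adj[rec].mean(axis=0)
    mu2 = X_adj[non].mean(axis=0)
    modes = estimate_mode_covariances(
        X_adj,
        labels,
        ridge_eps=settings.ridge_eps,
        tol=settings.flipflop_tol,
        max_iter=settings.flipflop_max_iter,
    )
    return {
        "alpha": alpha,
        "X_adj": X_adj,
        "gamma": gamma,
        "phi1": phi1,
        "phi2": phi2,
        "psi": psi,
        "mu1": mu1,
        "mu2": mu2,
        "D": mu1 - mu2,
        "modes": modes,
    }


def _margins(core, X, U):
    """Score minus intercept (enough for AUC-based penalty selection)."""
    X_adj = adjust_tensor(X, U, core["alpha"]) if core["gamma"].size else X
    lin = np.tensordot(X_adj, np.asarray(core["B"]), axes=([1, 2], [0, 1]))
    if core["gamma"].size:
        lin = lin + U @ core["gamma"]
    return lin


def _cv_choose_lambda(X, U, labels, lams, settings):
    labels = np.asarray(labels)
    counts = np.bincount(labels)[1:3]
    folds = int(min(settings.cv_folds, counts.min()))
    if folds < 2:
        raise CatchError("too few patients per class for cross-validation")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=settings.cv_seed)
    aucs = np.zeros((folds, len(lams)))
    for f, (tr, va) in enumerate(skf.split(np.zeros(labels.size), labels)):
        core = _fit_core(X[tr], None if U is None else U[tr], labels[tr], settings)
        path = _solve_down_path(
            core["D"],
            core["modes"].sigma1,
            core["modes"].sigma2,
            lams,
            settings.cd_tol,
            settings.cd_max_sweeps,
        )
        y_val = labels[va] == RECURRENT
        for k, (_, Bk, _) in enumerate(path):
            probe = dict(core, B=Bk)
            m = _margins(probe, X[va], None if U is None else U[va])
            aucs[f, k] = roc_auc_score(y_val, m) if len(set(y_val)) == 2 else np.nan
    mean_auc = np.nanmean(aucs, axis=0)
    best = int(np.argmax(mean_auc))  # path is sorted descending: tie -> larger lam
    return lams[best], float(mean_auc[best])


def fit_catch(
    X: np.ndarray,
    U: np.ndarray | None,
    labels,
    settings: CatchSettings | None = None,
    index_map: FeatureIndexMap | None = None,
) -> CatchModel:
    """Fit the full covariate-adjusted tensor discriminant model.

    ``X`` is the n x p1 x p2 image stack (typically min-max scaled),
    ``U`` the n x q covariate matrix (``None`` or empty for plain tensor
    discriminant analysis), ``labels`` coded 1 = recurrent / 2 = not.
    """
    settings = settings or CatchSettings()
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    if U is not None and np.size(U) == 0:
        U = None
    if U is not None:
        U = np.asarray(U, dtype=float)
        if U.shape[1] >= X.shape[0]:
            raise CatchError(
                f"q={U.shape[1]} covariates with n={X.shape[0]} patients; "
                "select fewer covariates (q must be < n)"
            )
    rec, non = _class_masks(labels)
    if rec.sum() < 3 or non.sum() < 3:
        raise CatchError("each class needs >= 3 patients")

    core = _fit_core(X, U, labels, settings)
    D = core["D"]
    S1, S2 = core["modes"].sigma1, core["modes"].sigma2

    lam_max = float(np.abs(D).max())
    cv_auc = None
    converged = True
    if lam_max == 0.0:
        lam, B = 0.0, np.zeros_like(D)
    else:
        lams = lambda_path(D, settings.n_lambdas, settings.lambda_min_ratio)
        if settings.lambda_rule == "fixed":
            lam = float(settings.fixed_lambda)
            lams = np.append(lams[lams > lam], lam)
        elif settings.lambda_rule == "cv":
            lam, cv_auc = _cv_choose_lambda(X, U, labels, lams, settings)
            lams = lams[lams >= lam]
        path = _solve_down_path(D, S1, S2, lams, settings.cd_tol, settings.cd_max_sweeps)
        if settings.lambda_rule == "sparsity":
            eligible = [
                (lam_k, Bk, ck)
                for lam_k, Bk, ck in path
                if np.count_nonzero(Bk) <= settings.s_target
            ]
            lam, B, converged = eligible[-1]  # smallest penalty within budget
        else:
            lam, B, converged = path[-1]
        if not converged:
            warnings.warn(
                "coordinate descent did not fully converge at the chosen "
                "penalty; model flagged",
                RuntimeWarning,
            )

    pi1 = rec.sum() / labels.size
    pi2 = non.sum() / labels.size
    intercept = float(
        np.log(pi1 / pi2)
        - 0.5 * np.sum(B * (core["mu1"] + core["mu2"]))
        - (
            0.5 * core["gamma"] @ (core["phi1"] + core["phi2"])
            if core["gamma"].size
            else 0.0
        )
    )
    return CatchModel(
        alpha=core["alpha"],
        gamma=core["gamma"],
        B=B,
        intercept=intercept,
        pi1=float(pi1),
        pi2=float(pi2),
        phi1=core["phi1"],
        phi2=core["phi2"],
        psi=core["psi"],
        mu1=core["mu1"],
        mu2=core["mu2"],
        sigma1=S1,
        sigma2=S2,
        lam=float(lam),
        index_map=index_map,
        settings=settings,
        converged=bool(converged),
        cv_auc=cv_auc,
    )


def predict(
    model: CatchModel, X: np.ndarray, U: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Scores, class labels and posteriors for new patients.

    ``score = a + gamma' U + <B, X - alpha xbar_3 U>``; positive scores
    predict recurrence (class 1), ties go to non-recurrent (class 2), and
    the posterior is the logistic transform of the score.
    """
    if not getattr(model, "fitted", False):
        raise CatchError("model is not fitted")
    X = np.asarray(X, dtype=float)
    if X.ndim == 2:
        X = X[None]
    if model.q > 0:
        if U is None:
            raise CatchError("model was fitted with covariates; U is required")
        U = np.asarray(U, dtype=float)
        if U.ndim == 1:
            U = U[None]
        X_adj = adjust_tensor(X, U, model.alpha)
        cov_term = U @ model.gamma
    else:
        X_adj = X
        cov_term = 0.0
    scores = (
        model.intercept
        + cov_term
        + np.tensordot(X_adj, model.B, axes=([1, 2], [0, 1]))
    )
    classes = np.where(scores > 0, RECURRENT, NON_RECURRENT)
    return scores, classes, expit(scores)


def rank_selected_features(
    model: CatchModel, index_map: FeatureIndexMap | None = None
) -> pd.DataFrame:
    """Nonzero discriminant coefficients as named features, |coef| descending.

    Positive coefficients associate the feature with recurrence.  Padded
    cells can never appear: their class-mean difference is identically zero,
    so soft-thresholding leaves them at zero.
    """
    if not getattr(model, "fitted", False):
        raise CatchError("model is not fitted")
    index_map = index_map or model.index_map
    rows = []
    nz = np.argwhere(model.B != 0.0)
    for i, j in nz:
        if index_map is not None:
            name = index_map.name_of(int(i), int(j))
            if name is None:
                name = f"pad_{i}_{j}"
        else:
            name = f"cell_{i}_{j}"
        rows.append((name, int(i), int(j), float(model.B[i, j])))
    frame = pd.DataFrame(rows, columns=["feature_name", "row", "col", "coefficient"])
    return frame.sort_values(
        "coefficient", key=lambda s: s.abs(), ascending=False, kind="mergesort"
    ).reset_index(drop=True)
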