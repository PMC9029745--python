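"""Resampling benchmark of the tensor classifier against comparators.

The default scheme follows the emulated study: 100 random stratified
67/33 train/test splits, with the training prevalence preserved by
largest-remainder rounding, and per-split accuracy, sensitivity,
specificity, F1 and AUC (positive class = recurrent).  A 3-fold
cross-validation scheme is available as an alternative.

Comparators: a random forest (standard library implementation, fixed
seed, default hyperparameters) and a diagonal-covariance LDA on the
concatenated vectorized image plus covariates — plain LDA is singular at
p >> n, so the diagonal variant stands in for it, as a documented
deviation.  Every method sees identical splits, and all training-time
statistics (scaler, size factors, covariate selection, model fit) are
computed on the training portion only when ``nested=True``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from . import degs
from .catch import CatchSettings, fit_catch, predict
from .cohort import CohortBundle
from .tensorize import fit_scaler, tensorize_table

__all__ = [
    "EvaluationError",
    "stratified_split",
    "compute_metrics",
    "DiagonalLDA",
    "EvalReport",
    "run_benchmark",
]

RECURRENT, NON_RECURRENT = 1, 2
METRICS = ("accuracy", "sensitivity", "specificity", "f1", "auc")


class EvaluationError(ValueError):
    pass


def stratified_split(
    labels, train_frac: float = 0.67, seed: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Random stratified split with largest-remainder per-class rounding.

    The total training size is ``round(train_frac * n)``; class quotas are
    floored and leftover seats go to the largest fractional remainders, so
    the training prevalence matches the cohort prevalence to within one
    patient.
    """
    labels = np.asarray(labels)
    n = labels.size
    if not 0.0 < train_frac < 1.0:
        raise EvaluationError("train_frac must be strictly between 0 and 1")
    classes, counts = np.unique(labels, return_counts=True)
    if counts.min() < 2:
        raise EvaluationError("each class needs >= 2 patients to split")
    n_train = int(round(train_frac * n))
    quotas = train_frac * counts
    base = np.floor(quotas).astype(int)
    remainders = quotas - base
    take = base.copy()
    extra = n_train - base.sum()
    order = np.argsort(-remainders, kind="mergesort")  # ties -> class order
    if extra > 0:
        for k in order[:extra]:
            take[k] += 1
    elif extra < 0:
        for k in order[::-1][: -extra]:
            take[k] -= 1
    if (take < 1).any() or (counts - take < 1).any():
        raise EvaluationError("rounding emptied a class in train or test")
    rng = np.random.default_rng(seed)
    train: list[int] = []
    test: list[int] = []
    for cls, t in zip(classes, take):
        idx = np.flatnonzero(labels == cls)
        idx = rng.permutation(idx)
        train.extend(idx[:t])
        test.extend(idx[t:])
    return np.sort(np.array(train)), np.sort(np.array(test))


def compute_metrics(y_true, y_pred, scores=None) -> dict:
    """Confusion-based metrics plus tie-corrected AUC (positive = recurrent).

    With a single-class truth the AUC is reported as NaN (undefined) while
    the confusion metrics are still computed.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0 or y_true.size != y_pred.size:
        raise EvaluationError("labels must be non-empty and equal length")
    tp = int(np.sum((y_pred == RECURRENT) & (y_true == RECURRENT)))
    tn = int(np.sum((y_pred == NON_RECURRENT) & (y_true == NON_RECURRENT)))
    fp = int(np.sum((y_pred == RECURRENT) & (y_true == NON_RECURRENT)))
    fn = int(np.sum((y_pred == NON_RECURRENT) & (y_true == RECURRENT)))
    n = y_true.size
    pos, neg = tp + fn, tn + fp
    out = {
        "tp": tp, "tn": tn, "fp": fp, "fn": fn,
        "accuracy": (tp + tn) / n,
        "sensitivity": tp / pos if pos else np.nan,
        "specificity": tn / neg if neg else np.nan,
        "f1": 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else np.nan,
        "auc": np.nan,
    }
    if scores is not None and pos and neg:
        out["auc"] = float(roc_auc_score(y_true == RECURRENT, np.asarray(scores)))
    return out


@dataclass
class DiagonalLDA:
    """Two-class LDA with pooled per-feature variances (diagonal covariance)."""

    var_floor_frac: float = 1e-8
    mean1: np.ndarray | None = None
    mean2: np.ndarray | None = None
    pooled_var: np.ndarray | None = None
    log_prior_ratio: float = 0.0

    def fit(self, Z: np.ndarray, y) -> "DiagonalLDA":
        Z = np.asarray(Z, dtype=float)
        y = np.asarray(y)
        rec, non = y == RECURRENT, y == NON_RECURRENT
        if rec.sum() < 2 or non.sum() < 2:
            raise EvaluationError("DiagonalLDA needs >= 2 patients per class")
        self.mean1 = Z[rec].mean(axis=0)
        self.mean2 = Z[non].mean(axis=0)
        n1, n2 = rec.sum(), non.sum()
        var = (
            (n1 - 1) * Z[rec].var(axis=0, ddof=1)
            + (n2 - 1) * Z[non].var(axis=0, ddof=1)
        ) / (n1 + n2 - 2)
        floor = self.var_floor_frac * max(var.mean(), 1e-300)
        self.pooled_var = np.maximum(var, floor)
        self.log_prior_ratio = float(np.log(n1 / n2))
        return self

    def decision(self, Z: np.ndarray) -> np.ndarray:
        Z = np.asarray(Z, dtype=float)
        w = (self.mean1 - self.mean2) / self.pooled_var
        mid = 0.5 * (self.mean1 + self.mean2)
        return self.log_prior_ratio + (Z - mid) @ w

    def predict(self, Z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        s = self.decision(Z)
        return s, np.where(s > 0, RECURRENT, NON_RECURRENT)


@dataclass
class EvalReport:
    """Per-iteration metric rows plus aggregate mean/SD per method."""

    per_iteration: pd.DataFrame
    skipped: dict = field(default_factory=dict)
    config: dict = field(default_factory=dict)

    def aggregate(self) -> pd.DataFrame:
        grouped = self.per_iteration.groupby("method")[list(METRICS)]
        mean = grouped.mean()
        sd = grouped.std()
        out = mean.join(sd, lsuffix="_mean", rsuffix="_sd")
        return out.reset_index()

    def table1(self) -> pd.DataFrame:
        """Method x five-metric summary in the benchmark-table layout."""
        mean = self.per_iteration.groupby("method")[list(METRICS)].mean()
        mean.columns = ["Accuracy", "Sensitivity", "Specificity", "F1 score", "AUC"]
        return mean.round(2).reset_index().rename(columns={"method": "Methods"})


def _split_bundle(bundle: CohortBundle, train_idx, test_idx):
    rad = bundle.radiomics
    cnt = bundle.counts
    cli = bundle.clinical
    return (
        (rad.iloc[train_idx], None if cnt is None else cnt.iloc[train_idx],
         cli.iloc[train_idx]),
        (rad.iloc[test_idx], None if cnt is None else cnt.iloc[test_idx],
         cli.iloc[test_idx]),
    )


def _prepare_iteration(train, test, p1, p2, k_select, selected_genes, nested,
                       pseudo_count=1.0):
    """Scaler, covariates and image stacks with training-only statistics."""
    rad_tr, cnt_tr, cli_tr = train
    rad_te, cnt_te, cli_te = test
    y_tr = cli_tr["recurrence"].to_numpy()
    y_te = cli_te["recurrence"].to_numpy()

    scaler = fit_scaler(rad_tr)
    X_tr = tensorize_table(rad_tr, p1, p2, scaler=scaler)
    X_te = tensorize_table(rad_te, p1, p2, scaler=scaler)

    U_tr = U_te = None
    genes = []
    if cnt_tr is not None and k_select > 0:
        reference = degs.size_factor_reference(cnt_tr, pseudo_count=pseudo_count)
        sf_tr = degs.compute_size_factors(cnt_tr, reference, pseudo_count=pseudo_count)
        sf_te = degs.compute_size_factors(cnt_te, reference, pseudo_count=pseudo_count)
        if nested or selected_genes is None:
            table = degs.test_differential_expression(cnt_tr, y_tr, sf_tr)
            genes = degs.select_covariates(table, k_select)
        else:
            genes = list(selected_genes)
        L_tr = degs.log2_normalized(cnt_tr, sf_tr)[genes]
        L_te = degs.log2_normalized(cnt_te, sf_te)[genes]
        center, scale = L_tr.mean(axis=0), L_tr.std(axis=0).replace(0.0, 1.0)
        U_tr = ((L_tr - center) / scale).to_numpy()
        U_te = ((L_te - center) / scale).to_numpy()
    return X_tr, X_te, U_tr, U_te, y_tr, y_te, genes


def _flat_features(stack, U):
    Z = stack.values.reshape(stack.n, -1)
    if U is not None:
        Z = np.hstack([Z, U])
    return Z


def run_benchmark(
    bundle: CohortBundle,
    p1: int = 33,
    p2: int = 32,
    methods: tuple[str, ...] = ("catch", "dlda", "rf"),
    iterations: int = 100,
    train_frac: float = 0.67,
    k_select: int = 30,
    nested: bool = True,
    scheme: str = "split",
    catch_settings: CatchSettings | None = None,
    seed: int = 0,
) -> EvalReport:
    """Repeated stratified 67/33 benchmark (or ``scheme="cv3"`` folds).

    With ``nested=False`` (global mode) covariate genes are selected once
    on the full cohort before resampling, reproducing a global-selection
    protocol that leaks label information into the test folds; the default
    nested mode reselects them inside every training split.
    """
    if scheme not in ("split", "cv3"):
        raise EvaluationError(f"unknown scheme {scheme!r}")
    labels = bundle.labels
    if bundle.counts is None:
        k_select = 0
    selected_global = None
    if not nested and bundle.counts is not None and k_select > 0:
        table = degs.test_differential_expression(
            bundle.counts, labels, pseudo_count=1.0
        )
        selected_global = degs.select_covariates(table, k_select)

    children = np.random.SeedSequence(seed).spawn(iterations)
    rows = []
    skipped: dict[str, int] = {m: 0 for m in methods}
    for it, child in enumerate(children):
        state = child.generate_state(3)
        split_seed = int(state[0] % (2**31))
        rf_seed = int(state[1] % (2**31))
        cv_seed = int(state[2] % (2**31))
        if scheme == "split":
            pairs = [stratified_split(labels, train_frac, seed=split_seed)]
        else:
            skf = StratifiedKFold(n_splits=3, shuffle=True, random_state=split_seed)
            pairs = list(skf.split(np.zeros(labels.size), labels))
        for train_idx, test_idx in pairs:
            train, test = _split_bundle(bundle, train_idx, test_idx)
            X_tr, X_te, U_tr, U_te, y_tr, y_te, genes = _prepare_iteration(
                train, test, p1, p2, k_select, selected_global, nested
            )
            for method in methods:
                try:
                    row = _run_method(
                        method, X_tr, X_te, U_tr, U_te, y_tr, y_te,
                        catch_settings, rf_seed, cv_seed,
                    )
                except Exception:  # noqa: BLE001 - logged and skipped
                    skipped[method] += 1
                    continue
                row.update({"iteration": it, "method": method,
                            "split_seed": split_seed})
                rows.append(row)
    report = EvalReport(
        per_iteration=pd.DataFrame(rows),
        skipped=skipped,
        config={
            "iterations": iterations, "train_frac": train_frac,
            "k_select": k_select, "nested": nested, "scheme": scheme,
            "seed": seed, "methods": list(methods),
        },
    )
    return report


def _run_method(method, X_tr, X_te, U_tr, U_te, y_tr, y_te,
                catch_settings, rf_seed, cv_seed):
    if method == "catch":
        settings = catch_settings or CatchSettings()
        if settings.lambda_rule == "cv":
            settings = CatchSettings(**{**settings.__dict__, "cv_seed": cv_seed})
        model = fit_catch(X_tr.values, U_tr, y_tr, settings=settings,
                          index_map=X_tr.index_map)
        scores, classes, _ = predict(model, X_te.values, U_te)
        row = compute_metrics(y_te, classes, scores)
        row["chosen_lambda"] = model.lam
        row["n_selected"] = model.n_selected()
        return row
    if method == "dlda":
        Z_tr = _flat_features(X_tr, U_tr)
        Z_te = _flat_features(X_te, U_te)
        lda = DiagonalLDA().fit(Z_tr, y_tr)
        scores, classes = lda.predict(Z_te)
        row = compute_metrics(y_te, classes, scores)
    elif method == "rf":
        Z_tr = _flat_features(X_tr, U_tr)
        Z_te = _flat_features(X_te, U_te)
        clf = RandomForestClassifier(random_state=rf_seed)
        clf.fit(Z_tr, y_tr)
        proba = clf.predict_proba(Z_te)[:, list(clf.classes_).index(RECURRENT)]
        classes = np.where(proba > 0.5, RECURRENT, NON_RECURRENT)
        row = compute_metrics(y_te, classes, proba)
    else:
        raise EvaluationError(f"unknown method {method!r}")
    row["chosen_lambda"] = np.nan
    row["n_selected"] = np.nan
    return row
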