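"""Differential-expression screening of immune-gene counts.

Selects the covariate genes that enter the discriminant model: counts are
normalized by median-of-ratios size factors, each gene is tested between
recurrence classes with a Welch two-sample t-test on log2(normalized
count + 1), p-values are BH-corrected across genes, and the ``k_select``
genes with the smallest q-values become covariates.

The stage is a self-contained stand-in with the same interface and output
as a negative-binomial DE workflow: the downstream model only consumes the
ranked gene list and log2-normalized expression.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DEGError",
    "size_factor_reference",
    "compute_size_factors",
    "log2_normalized",
    "test_differential_expression",
    "select_covariates",
]

RECURRENT, NON_RECURRENT = 1, 2


class DEGError(ValueError):
    pass


def _count_frame(counts) -> pd.DataFrame:
    frame = pd.DataFrame(counts)
    values = frame.to_numpy(dtype=float)
    if (values < 0).any():
        raise DEGError("counts must be non-negative")
    return frame


def size_factor_reference(counts, pseudo_count: float = 0.0) -> pd.Series:
    """Per-gene log geometric means over the reference (training) patients.

    Only genes with all-positive counts enter the reference, as in the
    median-of-ratios construction.  With ``pseudo_count`` > 0 every gene
    qualifies.
    """
    frame = _count_frame(counts)
    values = frame.to_numpy(dtype=float) + pseudo_count
    positive = (values > 0).all(axis=0)
    if not positive.any():
        raise DEGError(
            "no gene has all-positive counts; use pseudo-count mode "
            "(pseudo_count > 0)"
        )
    log_geo = np.full(frame.shape[1], np.nan)
    log_geo[positive] = np.log(values[:, positive]).mean(axis=0)
    return pd.Series(log_geo, index=frame.columns, name="log_geomean")


def compute_size_factors(
    counts,
    reference: pd.Series | None = None,
    pseudo_count: float = 0.0,
) -> pd.Series:
    """Median-of-ratios size factors (one per patient).

    ``factor_i = median_g count_ig / geomean_g`` over genes with a defined
    reference.  Passing a training-set ``reference`` lets held-out patients
    be normalized without touching training statistics.
    """
    frame = _count_frame(counts)
    if reference is None:
        reference = size_factor_reference(frame, pseudo_count=pseudo_count)
    reference = reference.reindex(frame.columns)
    usable = reference.notna().to_numpy()
    if not usable.any():
        raise DEGError("size-factor reference shares no genes with the counts")
    values = frame.to_numpy(dtype=float) + pseudo_count
    with np.errstate(divide="ignore"):
        log_ratios = np.log(values[:, usable]) - reference.to_numpy()[usable]
    factors = np.exp(np.median(log_ratios, axis=1))
    if not np.all(np.isfinite(factors)) or (factors <= 0).any():
        raise DEGError(
            "non-positive size factor; a patient has zero counts in every "
            "reference gene (use pseudo-count mode)"
        )
    return pd.Series(factors, index=frame.index, name="size_factor")


def log2_normalized(counts, size_factors: pd.Series) -> pd.DataFrame:
    """log2(count / size_factor + 1) expression matrix (patients x genes)."""
    frame = _count_frame(counts)
    sf = size_factors.reindex(frame.index).to_numpy(dtype=float)
    return pd.DataFrame(
        np.log2(frame.to_numpy(dtype=float) / sf[:, None] + 1.0),
        index=frame.index,
        columns=frame.columns,
    )


def test_differential_expression(
    counts,
    labels,
    size_factors: pd.Series | None = None,
    pseudo_count: float = 0.0,
) -> pd.DataFrame:
    """Per-gene Welch t-test on log2-normalized counts, BH across genes.

    Returns one row per gene: base_mean (mean normalized count), log2fc
    (recurrent minus non-recurrent class mean on the log2 scale), Welch
    statistic, p-value, BH q-value, and a ``selected`` flag (all False
    until :func:`select_covariates` runs).
    """
    frame = _count_frame(counts)
    labels = np.asarray(labels)
    if labels.shape[0] != frame.shape[0]:
        raise DEGError("labels length != patient count")
    rec = labels == RECURRENT
    non = labels == NON_RECURRENT
    if rec.sum() < 2 or non.sum() < 2:
        raise DEGError("each class needs >= 2 patients (variance undefined)")
    if size_factors is None:
        size_factors = compute_size_factors(frame, pseudo_count=pseudo_count)
    norm = frame.to_numpy(dtype=float) / size_factors.to_numpy()[:, None]
    log2n = np.log2(norm + 1.0)
    a, b = log2n[rec], log2n[non]
    with np.errstate(invalid="ignore", divide="ignore"):
        stat, pval = stats.ttest_ind(a, b, axis=0, equal_var=False)
    stat = np.asarray(stat, dtype=float)
    pval = np.asarray(pval, dtype=float)
    # zero within-class variance in both groups: no evidence either way
    degenerate = ~np.isfinite(stat)
    stat[degenerate] = 0.0
    pval[degenerate] = 1.0
    qval = multipletests(pval, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "gene": list(frame.columns),
            "base_mean": norm.mean(axis=0),
            "log2fc": a.mean(axis=0) - b.mean(axis=0),
            "stat": stat,
            "pvalue": pval,
            "qvalue": qval,
            "selected": False,
        }
    )


def select_covariates(deg: pd.DataFrame, k_select: int = 30) -> list[str]:
    """The ``k_select`` genes with smallest q-value.

    Ties are broken by larger |log2fc|, then lexicographic gene id; the
    ``selected`` column of ``deg`` is updated in place.
    """
    if k_select > len(deg):
        raise DEGError(f"k_select={k_select} exceeds gene count {len(deg)}")
    order = deg.assign(_abs_fc=-deg["log2fc"].abs()).sort_values(
        ["qvalue", "_abs_fc", "gene"], kind="mergesort"
    )
    chosen = list(order["gene"].iloc[:k_select])
    deg["selected"] = deg["gene"].isin(chosen)
    return chosen
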