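"""Downstream association analyses on adjusted radiomic features.

After the discriminant model selects pixels, three analyses carry the
adjusted features (pixels of ``X_adj = X - alpha xbar_3 U``) forward:

* rank-sum contrasts of a feature between recurrence classes, run in
  parallel on the unadjusted pixel values for the adjusted-vs-raw
  comparison;
* Kaplan-Meier recurrence-free-survival curves with a two-group log-rank
  test, grouping patients by the feature's median (ties to the low group);
* a feature x gene correlation map (Pearson by default, Spearman option)
  between adjusted pixel values and log2-normalized expression of the
  selected genes, BH-corrected across all pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _lifelines_logrank
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DownstreamError",
    "GroupCompareResult",
    "group_compare",
    "median_split",
    "SurvivalFit",
    "km_estimate",
    "logrank_test",
    "CorrelationMap",
    "correlate_features_genes",
]

RECURRENT, NON_RECURRENT = 1, 2


class DownstreamError(ValueError):
    pass


@dataclass
class GroupCompareResult:
    statistic: float  # Wilcoxon rank-sum W of the first (recurrent) group
    pvalue: float
    zero_variance: bool = False
    method: str = "asymptotic"

    def __iter__(self):
        return iter((self.statistic, self.pvalue))


def group_compare(values, labels) -> GroupCompareResult:
    """Two-sided Wilcoxon rank-sum test between recurrence classes.

    Small tie-free samples (both groups <= 8) use the exact null
    distribution; otherwise the normal approximation with continuity and
    tie correction applies.  Identical values in every patient give p = 1
    with a zero-variance flag.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    a = values[labels == RECURRENT]
    b = values[labels == NON_RECURRENT]
    if a.size < 2 or b.size < 2:
        raise DownstreamError("both groups need >= 2 patients")
    w_offset = a.size * (a.size + 1) / 2.0
    if np.ptp(values) == 0.0:
        return GroupCompareResult(
            statistic=float(a.size * b.size / 2.0 + w_offset),
            pvalue=1.0,
            zero_variance=True,
            method="degenerate",
        )
    has_ties = np.unique(values).size < values.size
    method = "exact" if (max(a.size, b.size) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=True
    )
    return GroupCompareResult(
        statistic=float(res.statistic + w_offset),
        pvalue=float(min(res.pvalue, 1.0)),
        method=method,
    )


def median_split(values) -> np.ndarray:
    """"low" for values <= median (ties to low), "high" otherwise."""
    values = np.asarray(values, dtype=float)
    med = np.median(values)
    return np.where(values <= med, "low", "high")


@dataclass
class SurvivalFit:
    """Product-limit estimate for one group."""

    group: str
    times: np.ndarray            # distinct event times, ascending
    at_risk: np.ndarray
    events: np.ndarray
    survival: np.ndarray
    censor_times: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "at_risk": self.at_risk,
                "events": self.events,
                "survival": self.survival,
            }
        ).assign(group=self.group)

    def survival_at(self, t: float) -> float:
        mask = self.times <= t
        return float(self.survival[mask][-1]) if mask.any() else 1.0


def _km_single(time, event, group_label: str) -> SurvivalFit:
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=event, label=group_label)
    table = kmf.event_table
    event_rows = table[table["observed"] > 0]
    surv = kmf.survival_function_at_times(event_rows.index).to_numpy()
    return SurvivalFit(
        group=group_label,
        times=event_rows.index.to_numpy(dtype=float),
        at_risk=event_rows["at_risk"].to_numpy(dtype=float),
        events=event_rows["observed"].to_numpy(dtype=float),
        survival=surv,
        censor_times=np.asarray(time)[np.asarray(event) == 0].astype(float),
    )


def km_estimate(time, event, group=None) -> dict[str, SurvivalFit]:
    """Kaplan-Meier estimates per group (or one "all" group).

    Censored patients leave the risk set without producing a step; the
    curve starts at 1 and is non-increasing.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    if (time < 0).any():
        raise DownstreamError("negative survival time")
    if group is None:
        return {"all": _km_single(time, event, "all")}
    group = np.asarray(group)
    return {
        str(g): _km_single(time[group == g], event[group == g], str(g))
        for g in pd.unique(group)
    }


def logrank_test(time, event, group) -> tuple[float, float]:
    """Standard two-group log-rank test (chi-square statistic, df = 1)."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    group = np.asarray(group)
    levels = pd.unique(group)
    if len(levels) != 2:
        raise DownstreamError(f"log-rank needs exactly 2 groups, got {len(levels)}")
    m = group == levels[0]
    res = _lifelines_logrank(time[m], time[~m], event[m], event[~m])
    return float(res.test_statistic), float(res.p_value)


@dataclass
class CorrelationMap:
    """Feature x gene correlations with p- and BH q-values."""

    r: pd.DataFrame
    p: pd.DataFrame
    q: pd.DataFrame
    method: str = "pearson"
    skipped: list = field(default_factory=list)

    def long_format(self) -> pd.DataFrame:
        rows = []
        for feat in self.r.index:
            for gene in self.r.columns:
                rows.append(
                    (feat, gene, self.r.loc[feat, gene],
                     self.p.loc[feat, gene], self.q.loc[feat, gene])
                )
        return pd.DataFrame(rows, columns=["feature", "gene", "r", "p", "q"])


def correlate_features_genes(
    features: pd.DataFrame,
    genes: pd.DataFrame,
    method: str = "pearson",
) -> CorrelationMap:
    """Correlation of each (adjusted feature, gene expression) pair.

    Positive coefficients mean expression rises with the adjusted feature
    value.  Constant columns cannot be correlated; those pairs are skipped
    (NaN) and listed in ``skipped``.  BH correction runs across all tested
    pairs.
    """
    if method not in ("pearson", "spearman"):
        raise DownstreamError(f"unknown correlation method {method!r}")
    if len(features) != len(genes):
        raise DownstreamError("feature and gene tables disagree on patients")
    if len(features) < 3:
        raise DownstreamError("need n >= 3 patients to correlate")
    corr = stats.pearsonr if method == "pearson" else stats.spearmanr
    feats = features.columns
    gene_cols = genes.columns
    r = pd.DataFrame(np.nan, index=feats, columns=gene_cols)
    p = pd.DataFrame(np.nan, index=feats, columns=gene_cols)
    skipped = []
    const_feats = {f for f in feats if np.ptp(features[f].to_numpy()) == 0.0}
    const_genes = {g for g in gene_cols if np.ptp(genes[g].to_numpy()) == 0.0}
    pvals, where = [], []
    for f in feats:
        x = features[f].to_numpy(dtype=float)
        for g in gene_cols:
            if f in const_feats or g in const_genes:
                skipped.append((f, g))
                continue
            res = corr(x, genes[g].to_numpy(dtype=float))
            r.loc[f, g] = res.statistic if hasattr(res, "statistic") else res[0]
            pv = res.pvalue if hasattr(res, "pvalue") else res[1]
            p.loc[f, g] = pv
            pvals.append(pv)
            where.append((f, g))
    q = pd.DataFrame(np.nan, index=feats, columns=gene_cols)
    if pvals:
        qvals = multipletests(pvals, method="fdr_bh")[1]
        for (f, g), qv in zip(where, qvals):
            q.loc[f, g] = qv
    return CorrelationMap(r=r, p=p, q=q, method=method, skipped=skipped)
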