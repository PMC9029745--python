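"""Rank-sum contrasts, product-limit survival, log-rank and correlation maps."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from radcatch import SimConfig, generate_cohort_like, generate_model_exact
from radcatch.catch import adjust_tensor
from radcatch.downstream import (
    DownstreamError,
    correlate_features_genes,
    group_compare,
    km_estimate,
    logrank_test,
    median_split,
)
from radcatch.tensorize import tensorize_table


def _labels(n1, n2):
    return np.r_[np.ones(n1, int), np.full(n2, 2)]


class TestGroupCompare:
    def test_extreme_separation_matches_exact_enumeration(self):
        """p at n=3+3 equals the brute-force permutation tail probability."""
        values = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        labels = _labels(3, 3)
        res = group_compare(values, labels)
        # brute force: rank-sum of every 3-subset of the pooled ranks
        ranks = np.arange(1, 7)
        sums = [sum(c) for c in combinations(ranks, 3)]
        observed = values[:3].sum()  # ranks equal values here; W = 6
        lo = np.mean([s <= observed for s in sums])
        hi = np.mean([s >= observed for s in sums])
        exact_p = 2 * min(lo, hi)
        assert res.method == "exact"
        assert res.pvalue == pytest.approx(exact_p)  # = 0.1
        assert res.statistic == 6.0  # rank-sum at its minimum

    def test_identical_values_flag_zero_variance(self):
        res = group_compare(np.full(8, 3.3), _labels(4, 4))
        assert res.pvalue == 1.0 and res.zero_variance

    def test_type_one_error_calibrated(self, rng):
        rejections = 0
        reps = 1000
        for _ in range(reps):
            values = rng.standard_normal(71)
            labels = rng.permutation(_labels(21, 50))
            rejections += group_compare(values, labels).pvalue < 0.05
        assert 0.03 <= rejections / reps <= 0.07

    def test_tiny_groups_rejected(self):
        with pytest.raises(DownstreamError):
            group_compare(np.arange(4.0), np.array([1, 2, 2, 2]))


class TestKaplanMeier:
    def test_three_patient_hand_example(self):
        fits = km_estimate([1.0, 2.0, 3.0], [1, 1, 0])
        fit = fits["all"]
        np.testing.assert_array_equal(fit.times, [1.0, 2.0])
        np.testing.assert_allclose(fit.survival, [2 / 3, 1 / 3])
        assert fit.survival_at(2.5) == pytest.approx(1 / 3)  # flat after t=2
        assert fit.survival_at(0.5) == 1.0

    def test_no_events_keeps_survival_at_one(self):
        fit = km_estimate([2.0, 4.0, 9.0], [0, 0, 0])["all"]
        assert fit.times.size == 0
        assert fit.survival_at(100.0) == 1.0

    def test_all_events_distinct_times_closed_form(self):
        n = 6
        fit = km_estimate(np.arange(1.0, n + 1), np.ones(n, int))["all"]
        np.testing.assert_allclose(fit.survival, (n - np.arange(1, n + 1)) / n)
        # risk set strictly decreasing over the listed event times
        assert (np.diff(fit.at_risk) < 0).all()

    def test_grouped_fit_is_non_increasing_from_one(self, rng):
        time = rng.exponential(10.0, size=40)
        event = rng.integers(0, 2, size=40)
        group = np.where(rng.random(40) < 0.5, "low", "high")
        fits = km_estimate(time, event, group)
        for fit in fits.values():
            assert (np.diff(fit.survival) <= 1e-12).all()
            assert fit.survival.size == 0 or fit.survival[0] <= 1.0


class TestLogrank:
    def test_identical_duplicated_groups_give_zero_statistic(self):
        time = np.r_[[1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0]]
        event = np.r_[[1, 0, 1, 1], [1, 0, 1, 1]]
        group = np.r_[np.zeros(4), np.ones(4)]
        stat, p = logrank_test(time, event, group)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_null_statistic_mean_is_about_one(self, rng):
        """Chi-square(1) null: the statistic's mean over reps is ~1."""
        stats = []
        for _ in range(1000):
            time = rng.exponential(12.0, size=40)
            event = (rng.random(40) < 0.7).astype(int)
            group = rng.permutation(np.r_[np.zeros(20), np.ones(20)])
            stats.append(logrank_test(time, event, group)[0])
        assert np.mean(stats) == pytest.approx(1.0, abs=0.15)

    def test_power_when_hazard_tracks_score(self):
        significant = 0
        for seed in range(20):
            config = SimConfig.strong(
                n=200, p1=4, p2=3, n_features=12, q=3, g_total=20, g_de=3,
                exact_prevalence=True, seed=700 + seed,
            )
            bundle, truth = generate_cohort_like(config)
            groups = median_split(truth.scores)
            _, p = logrank_test(bundle.clinical["rfs_months"],
                                bundle.clinical["event"], groups)
            significant += p < 0.05
        assert significant >= 18  # >= 90% of 20 seeds

    def test_median_split_ties_go_low(self):
        groups = median_split([1.0, 2.0, 2.0, 3.0])
        assert list(groups) == ["low", "low", "low", "high"]


class TestCorrelation:
    def test_identical_and_negated_columns(self):
        feats = pd.DataFrame({"f": [1.0, 2.0, 3.0, 4.0]})
        genes = pd.DataFrame({"same": [1.0, 2.0, 3.0, 4.0],
                              "neg": [-1.0, -2.0, -3.0, -4.0]})
        cmap = correlate_features_genes(feats, genes)
        assert cmap.r.loc["f", "same"] == pytest.approx(1.0)
        assert cmap.r.loc["f", "neg"] == pytest.approx(-1.0)

    def test_three_point_hand_example(self):
        cmap = correlate_features_genes(
            pd.DataFrame({"f": [1.0, 2.0, 3.0]}),
            pd.DataFrame({"g": [2.0, 1.0, 3.0]}),
        )
        assert cmap.r.loc["f", "g"] == pytest.approx(0.5)

    def test_constant_column_skipped_with_flag(self):
        cmap = correlate_features_genes(
            pd.DataFrame({"f": [1.0, 2.0, 3.0]}),
            pd.DataFrame({"g": [5.0, 5.0, 5.0], "h": [1.0, 0.0, 2.0]}),
        )
        assert ("f", "g") in cmap.skipped
        assert np.isnan(cmap.r.loc["f", "g"])
        assert np.isfinite(cmap.r.loc["f", "h"])

    def test_alpha_driven_gene_pixel_link_ranks_highest(self):
        """A gene wired to a pixel through alpha dominates that pixel's map."""
        top_hits = 0
        for seed in range(20):
            alpha = np.zeros((4, 3, 3))
            alpha[1, 1, 0] = 1.5  # gene 0 drives pixel (1, 1)
            config = SimConfig(
                n=150, p1=4, p2=3, n_features=12, q=3, g_total=12, g_de=3,
                alpha_true=alpha, s_true=0, b_scale=0.0, gamma_scale=0.0,
                noise_scale=0.5, exact_prevalence=True, seed=900 + seed,
            )
            bundle, truth = generate_model_exact(config)
            X = tensorize_table(bundle.radiomics, 4, 3).values
            feats = pd.DataFrame({"px": X[:, 1, 1]})
            genes = pd.DataFrame(truth.U, columns=["g0", "g1", "g2"])
            cmap = correlate_features_genes(feats, genes)
            row = cmap.r.loc["px"]
            top_hits += (row.idxmax() == "g0") and (row["g0"] > 0)
        assert top_hits >= 18

    def test_adjusted_support_pixels_separate_better_than_off_support(self):
        """Group tests on true-support pixels of X_adj reject more often."""
        config = SimConfig(
            n=120, p1=5, p2=4, n_features=20, q=3, g_total=12, g_de=3,
            s_true=3, b_scale=1.0, alpha_scale=0.5, alpha_links=6,
            gamma_scale=0.5, prevalence=0.4, exact_prevalence=True, seed=17,
        )
        on_p, off_p = [], []
        for seed in range(10):
            cfg = SimConfig(**{**config.__dict__, "seed": 1000 + seed})
            bundle, truth = generate_model_exact(cfg)
            X = tensorize_table(bundle.radiomics, 5, 4).values
            X_adj = adjust_tensor(X, truth.U, truth.alpha_true)
            support = truth.support()
            off = [(0, 0), (4, 3), (2, 2)]
            off = [c for c in off if c not in support][:2]
            for i, j in support:
                on_p.append(group_compare(X_adj[:, i, j], truth.labels).pvalue)
            for i, j in off:
                off_p.append(group_compare(X_adj[:, i, j], truth.labels).pvalue)
        assert np.mean(np.array(on_p) < 0.05) > np.mean(np.array(off_p) < 0.05)
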