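"""End-to-end pipeline: cohort -> DEGs -> model -> benchmark -> associations.

``run_pipeline`` orchestrates the full analysis and writes every artifact
into one result directory:

========================  =====================================================
deg_table.tsv             per-gene DE statistics (global selection)
selected_genes.txt        covariate gene ids, one per line
model.json                the fitted discriminant model (full cohort)
feature_ranking.tsv       nonzero coefficients as named features
metrics.tsv / .json       benchmark table (method x five metrics) and detail
group_tests.tsv           adjusted-vs-raw rank-sum contrasts per top feature
survival_<feature>.tsv    per-group product-limit tables (adjusted median split)
logrank.tsv               log-rank statistics per top feature
correlation_*.tsv         feature x gene correlation matrix and long format
config_echo.yaml          configuration, master seed and config hash
pipeline.log              stage log
========================  =====================================================

The full-cohort interpretive fit uses global covariate selection by
construction; the benchmark honors ``config.nested``.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import degs
from .catch import CatchSettings, fit_catch, rank_selected_features
from .cohort import CohortBundle
from .config import RunConfig
from .downstream import (
    correlate_features_genes,
    group_compare,
    km_estimate,
    logrank_test,
    median_split,
)
from .evaluate import run_benchmark
from .simulate import SimConfig, generate_cohort_like, write_cohort
from .tensorize import fit_scaler, tensorize_table
from .catch import adjust_tensor

logger = logging.getLogger("radcatch")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _settings_from_config(config: RunConfig, cv_seed: int = 0) -> CatchSettings:
    return CatchSettings(
        lambda_rule=config.lambda_rule,
        n_lambdas=config.n_lambdas,
        lambda_min_ratio=config.lambda_min_ratio,
        s_target=config.s_target,
        cv_folds=config.cv_folds,
        cv_seed=cv_seed,
        fixed_lambda=config.fixed_lambda,
        ridge_eps=config.ridge_eps,
        cd_tol=config.cd_tol,
        flipflop_tol=config.flipflop_tol,
    )


def simulate_bundle(config: RunConfig) -> tuple[CohortBundle, object]:
    preset = {
        "moderate": SimConfig,
        "null": SimConfig.null,
        "strong": SimConfig.strong,
    }[config.sim_preset]
    sim = preset(
        seed=config.seed,
        p1=config.p1,
        p2=config.p2,
        n_features=min(1037, config.p1 * config.p2),
    )
    return generate_cohort_like(sim)


def _safe_name(feature: str) -> str:
    return "".join(c if c.isalnum() or c in "-_" else "_" for c in feature)


def run_pipeline(
    config: RunConfig,
    outdir: str | Path,
    bundle: CohortBundle | None = None,
) -> Path:
    """Run every stage; artifacts land in ``outdir`` (partial on failure)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "pipeline.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    stage = "setup"
    try:
        config.to_yaml(outdir / "config_echo.yaml")
        logger.info("config hash %s, master seed %d", config.hash(), config.seed)

        stage = "cohort"
        truth = None
        if bundle is None:
            if not config.simulate:
                raise ValueError("no cohort given and simulate mode is off")
            bundle, truth = simulate_bundle(config)
            write_cohort(bundle, truth, outdir / "cohort", config.delimiter)
            logger.info("simulated %s cohort with n=%d", config.sim_preset, bundle.n)
        labels = bundle.labels

        stage = "covariate_selection"
        U = None
        genes: list[str] = []
        if bundle.counts is not None and config.k_select > 0:
            sf = degs.compute_size_factors(bundle.counts,
                                           pseudo_count=config.pseudo_count)
            deg_table = degs.test_differential_expression(bundle.counts, labels, sf)
            genes = degs.select_covariates(deg_table, config.k_select)
            deg_table.to_csv(outdir / "deg_table.tsv", sep="\t", index=False)
            (outdir / "selected_genes.txt").write_text("\n".join(genes) + "\n")
            expr = degs.log2_normalized(bundle.counts, sf)[genes]
            U = ((expr - expr.mean(axis=0)) /
                 expr.std(axis=0).replace(0.0, 1.0)).to_numpy()
            logger.info("selected %d covariate genes", len(genes))

        stage = "tensorization"
        scaler = fit_scaler(bundle.radiomics)
        stack = tensorize_table(bundle.radiomics, config.p1, config.p2, scaler=scaler)
        stack.index_map.to_json(outdir / "feature_map.json")

        stage = "model_fit"
        settings = _settings_from_config(config, cv_seed=config.seed)
        model = fit_catch(stack.values, U, labels, settings=settings,
                          index_map=stack.index_map)
        model.to_json(outdir / "model.json")
        ranking = rank_selected_features(model)
        ranking.to_csv(outdir / "feature_ranking.tsv", sep="\t", index=False)
        logger.info("model fit: lambda=%.4g, %d nonzero coefficients",
                    model.lam, model.n_selected())

        stage = "evaluation"
        report = run_benchmark(
            bundle,
            p1=config.p1,
            p2=config.p2,
            methods=tuple(config.methods),
            iterations=config.iterations,
            train_frac=config.train_frac,
            k_select=config.k_select,
            nested=config.nested,
            scheme=config.scheme,
            catch_settings=settings,
            seed=config.seed,
        )
        report.table1().to_csv(outdir / "metrics.tsv", sep="\t", index=False)
        report.per_iteration.to_json(outdir / "metrics.json", orient="records")
        logger.info("benchmark complete: %d rows, skipped %s",
                    len(report.per_iteration), report.skipped)

        stage = "downstream"
        X_adj = adjust_tensor(stack.values, U, model.alpha) if U is not None \
            else stack.values
        top = ranking.head(config.top_features)
        time = bundle.clinical["rfs_months"].to_numpy()
        event = bundle.clinical["event"].to_numpy()
        group_rows, logrank_rows = [], []
        for _, rec in top.iterrows():
            i, j, feat = int(rec["row"]), int(rec["col"]), rec["feature_name"]
            adj_vals = X_adj[:, i, j]
            raw_vals = stack.values[:, i, j]
            for kind, vals in (("adjusted", adj_vals), ("raw", raw_vals)):
                gc = group_compare(vals, labels)
                group_rows.append((feat, kind, gc.statistic, gc.pvalue, gc.method))
                groups = median_split(vals)
                stat, p = logrank_test(time, event, groups)
                logrank_rows.append((feat, kind, stat, p))
                if kind == "adjusted":
                    fits = km_estimate(time, event, groups)
                    frame = pd.concat([f.to_frame() for f in fits.values()])
                    frame.to_csv(outdir / f"survival_{_safe_name(feat)}.tsv",
                                 sep="\t", index=False)
        pd.DataFrame(group_rows,
                     columns=["feature", "kind", "ranksum_W", "p", "method"]
                     ).to_csv(outdir / "group_tests.tsv", sep="\t", index=False)
        pd.DataFrame(logrank_rows,
                     columns=["feature", "kind", "logrank_chi2", "p"]
                     ).to_csv(outdir / "logrank.tsv", sep="\t", index=False)

        if U is not None and len(top):
            feat_table = pd.DataFrame(
                {rec["feature_name"]: X_adj[:, int(rec["row"]), int(rec["col"])]
                 for _, rec in top.iterrows()},
                index=bundle.clinical.index,
            )
            expr = degs.log2_normalized(
                bundle.counts,
                degs.compute_size_factors(bundle.counts,
                                          pseudo_count=config.pseudo_count),
            )[genes]
            cmap = correlate_features_genes(feat_table, expr,
                                            method=config.correlation_method)
            cmap.r.to_csv(outdir / "correlation_matrix.tsv", sep="\t")
            cmap.long_format().to_csv(outdir / "correlation_long.tsv",
                                      sep="\t", index=False)
        logger.info("pipeline complete")
        return outdir
    except Exception as exc:  # noqa: BLE001
        logger.error("stage %s failed: %s", stage, exc)
        raise PipelineError(stage, exc) from exc
    finally:
        logger.removeHandler(handler)
        handler.close()
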