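"""End-to-end orchestration: simulate/load -> select -> fit -> tree -> policy.

``run_pipeline`` writes a reproducible artifact bundle (all plain text) and a
single machine-readable ``summary.json``; identical configurations and seeds
give byte-identical summaries.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path

import pandas as pd

from . import cohort, descriptives, dml, policy as policy_mod, tree as tree_mod
from .io import RunConfig, config_hash, load_visits, split_truth_columns, write_json
from .synthetic import SimConfig, simulate_cohort

log = logging.getLogger("psadose")

__all__ = ["run_pipeline"]

SCORE_BASELINES = (
    "psaid_baseline",
    "bdi_baseline",
    "phga_baseline",
    "pga_baseline",
    "spi2_baseline",
    "pasi_baseline",
    "crp_baseline",
)


def _stage(name):
    log.info("stage %s", name)
    return time.perf_counter()


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write the artifact bundle under ``config.out_dir``.

    Artifacts: visits.csv (+ truth.csv when simulated), exclusion_log.json,
    group_summary.csv, coefficient_table.csv, cate_model.json, tree.json,
    tree_leaves.csv, shift_matrix.csv, policy.json and summary.json.
    Returns the summary dict.  Any stage failure raises with the stage name.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"seed": int(config.seed), "config_hash": config_hash(config)}

    stage = "simulate/load"
    try:
        t0 = _stage(stage)
        if config.input_csv is not None:
            visits = load_visits(config.input_csv)
        else:
            sim = config.sim or SimConfig(seed=config.seed)
            visits = simulate_cohort(sim)
            observable, truth = split_truth_columns(visits)
            observable.to_csv(out / "visits.csv", index=False)
            truth.to_csv(out / "truth.csv", index=False)

        stage = "select_patients"
        t0 = _stage(stage)
        analysis, excl = cohort.select_patients(visits, outcome="psaid")
        if len(analysis) == 0:
            raise ValueError("no eligible patients after selection")
        write_json({**excl, **meta}, out / "exclusion_log.json")

        stage = "filter_variables"
        analysis, dropped = cohort.filter_variables(
            analysis, config.roles, config.max_missing_fraction
        )
        feature_cols = [c for c in config.roles.features if c in analysis.columns]
        analysis = cohort.impute_baseline(analysis, feature_cols)

        stage = "descriptives"
        t0 = _stage(stage)
        summary_tbl = descriptives.group_summary(
            analysis, [c for c in SCORE_BASELINES if c in analysis.columns]
        )
        summary_tbl.to_csv(out / "group_summary.csv", index=False)
        naive = descriptives.naive_effect(analysis)

        stage = "dml"
        t0 = _stage(stage)
        nuis = dml.fit_nuisances(
            analysis, config.roles, k=config.k_folds,
            learner=config.learner, seed=config.seed,
        )
        modifiers = [c for c in config.effect_modifiers if c in analysis.columns]
        model = dml.fit_linear_cate(
            analysis, nuis, effect_modifiers=modifiers, roles=config.roles
        )
        # global coefficient run over all available features (forest-plot analogue)
        feats = dml.prepare_features(analysis, config.roles)
        global_modifiers = [c for c in feats.columns if not c.endswith("_was_missing")]
        with_feats = pd.concat(
            [analysis, feats[[c for c in feats.columns if c not in analysis.columns]]],
            axis=1,
        )
        global_model = dml.fit_linear_cate(
            with_feats, nuis, effect_modifiers=global_modifiers,
            roles=config.roles, standardize=True,
        )
        dml.coefficient_table(global_model).to_csv(
            out / "coefficient_table.csv", index=False
        )
        write_json({**model.to_dict(), **meta}, out / "cate_model.json")
        iptw_ate, iptw_se = dml.estimate_ate_iptw(
            analysis[config.roles.y].to_numpy(float),
            analysis[config.roles.t].to_numpy(int),
            nuis.e_hat,
        )

        stage = "tree"
        t0 = _stage(stage)
        tree_cov = analysis[[c for c in feature_cols
                             if pd.api.types.is_numeric_dtype(analysis[c])]]
        root = tree_mod.build_tree(
            tree_cov, model.theta_hat,
            min_leaf=config.tree_min_leaf, max_depth=config.tree_max_depth,
        )
        write_json({**root.to_dict(), **meta}, out / "tree.json")
        tree_mod.flatten_tree(root).to_csv(out / "tree_leaves.csv", index=False)

        stage = "policy"
        t0 = _stage(stage)
        low = analysis[analysis[config.roles.t] == 0]
        shift = policy_mod.burden_shift(low, model.theta_hat[(analysis[config.roles.t] == 0).to_numpy()])
        shift.to_csv(out / "shift_matrix.csv")
        low_ref = float(low[config.roles.y].mean())
        reports = [
            policy_mod.recommend_policy(model.theta_hat, tau, reference_reduction=low_ref)
            for tau in config.policy_thresholds
        ]
        write_json(
            {"reports": [r.to_dict() for r in reports], **meta}, out / "policy.json"
        )

        stage = "summary"
        summary = {
            **meta,
            "n_visits_rows": int(len(visits)),
            "n_analysis": int(len(analysis)),
            "dropped_columns": dropped,
            "naive_effect": float(naive),
            "iptw_ate": float(iptw_ate),
            "iptw_se": float(iptw_se),
            "dml_average_cate": float(model.average_cate),
            "dml_beta": {n: float(b) for n, b in zip(model.feature_names, model.beta)},
            "tree_root_mean_cate": float(root.mean_cate),
            "policy_fractions": {
                str(r.threshold): float(r.fraction_high_dose) for r in reports
            },
        }
        if "_true_theta" in analysis.columns:
            summary["true_ate_sample"] = float(analysis["_true_theta"].mean())
        write_json(summary, out / "summary.json")
        log.info("pipeline done in %.1fs", time.perf_counter() - t0)
        return summary
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
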