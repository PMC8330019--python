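"""End-to-end orchestration: classify -> encode -> cluster -> stats -> tree.

`run_all` ties the stages together on a visits table and a baseline
covariate table (typically produced by :mod:`phenoresp.synthetic`), writes
every stage output under one directory, and returns the in-memory results
plus a YAML run manifest (config digest, seed, per-stage row counts,
excluded patients).
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import stats as cluster_stats
from .cluster import (
    ClusterAssignment,
    cut_tree,
    dendrogram_to_newick,
    distance_matrix,
    select_k_by_gap,
    ward_linkage,
)
from .response_rules import (
    ALL_INTERVALS,
    CLUSTERING_FEATURES,
    METRICS,
    ResponseRuleSet,
    build_response_profile,
    encode_matrix,
    profiles_to_frame,
    read_visits_csv,
)
from .tree import (
    TreeParams,
    confusion_matrix,
    feature_importance,
    fit_cart,
    predict,
    prepare_features,
    tree_to_dot,
    tree_to_json,
)

logger = logging.getLogger("phenoresp")

__all__ = ["PipelineConfig", "run_all", "validate_inputs"]


@dataclass
class PipelineConfig:
    """Run parameters for the full pipeline."""

    visits_csv: str = ""
    baseline_csv: str = ""
    out_dir: str = "phenoresp_out"
    rules: ResponseRuleSet = field(default_factory=ResponseRuleSet)
    k: int = 4
    alpha: float = 0.05
    tree: TreeParams = field(default_factory=TreeParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be at least 2")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


def validate_inputs(visits_csv, baseline_csv) -> dict:
    """Schema checks on the two input tables.

    Returns ``{"ok": bool, "violations": [messages...]}`` listing column,
    range and duplicate-key problems with row context.
    """
    violations = []
    visits = pd.read_csv(visits_csv, dtype={"patient_id": str})
    from .response_rules import VISIT_COLUMNS
    missing = set(VISIT_COLUMNS) - set(visits.columns)
    if missing:
        violations.append(f"visits: missing columns {sorted(missing)}")
    else:
        dup = visits.duplicated(subset=["patient_id", "visit_index"])
        for idx in visits.index[dup]:
            violations.append(f"visits row {idx}: duplicate (patient, visit) pair")
        bad_visit = ~visits["visit_index"].isin([0, 1, 2, 3])
        for idx in visits.index[bad_visit]:
            violations.append(f"visits row {idx}: visit_index outside 0..3")
        ctrl = visits["control_level"].dropna()
        for idx in ctrl.index[~ctrl.isin([0, 1, 2])]:
            violations.append(f"visits row {idx}: control_level outside {{0,1,2}}")
        for col in ("fev1_pp", "mef50_pp"):
            vals = visits[col].dropna()
            for idx in vals.index[(vals < 0) | (vals > 2)]:
                violations.append(f"visits row {idx}: {col} outside [0, 2]")
        feno = visits["feno_ppb"].dropna()
        for idx in feno.index[feno < 0]:
            violations.append(f"visits row {idx}: negative FENO")
    baselines = pd.read_csv(baseline_csv, dtype={"patient_id": str})
    if "patient_id" not in baselines.columns:
        violations.append("baselines: missing patient_id column")
    elif baselines["patient_id"].duplicated().any():
        violations.append("baselines: duplicated patient_id")
    if "archetype" in baselines.columns or any(
            c.startswith("true_") for c in baselines.columns):
        violations.append("baselines: truth label column leaked into analysis input")
    return {"ok": not violations, "violations": violations}


def run_all(config: PipelineConfig) -> dict:
    """Execute the full analysis and write all stage outputs.

    Stages: response classification -> coded-matrix encoding (complete
    cases) -> Ward clustering and k-cut -> cluster statistics (response
    features and baseline covariates) -> CART + feature importance.
    Returns a dict of stage results; the manifest is written as YAML.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = validate_inputs(config.visits_csv, config.baseline_csv)
    if not report["ok"]:
        raise ValueError("input validation failed: " + "; ".join(report["violations"]))

    visits = read_visits_csv(config.visits_csv)
    baselines = pd.read_csv(config.baseline_csv, dtype={"patient_id": str})
    ages = baselines.set_index("patient_id")["age_years"]

    profiles = [
        build_response_profile(patient_visits, float(ages.get(pid, np.nan)),
                               config.rules)
        for pid, patient_visits in visits.items()
    ]
    profile_frame = profiles_to_frame(profiles)
    profile_frame.to_csv(out / "response_profiles.csv", index=False)

    matrix, excluded = encode_matrix(profiles)
    matrix.to_frame().to_csv(out / "coded_matrix.csv")
    pd.DataFrame({"patient_id": excluded}).to_csv(out / "excluded_patients.csv",
                                                  index=False)
    logger.info("encoded %d complete cases (%d excluded)",
                len(matrix.patient_ids), len(excluded))

    dendrogram = ward_linkage(distance_matrix(matrix),
                              leaf_names=matrix.patient_ids)
    (out / "dendrogram.nwk").write_text(dendrogram_to_newick(dendrogram))
    assignment = cut_tree(dendrogram, config.k)
    assignment.to_series().rename_axis("patient_id").to_csv(out / "clusters.csv")
    advisory_k = select_k_by_gap(dendrogram, k_max=8)

    # cluster statistics: coded response features (categorical) plus the
    # cumulative-interval categories, then the baseline covariates
    coded = matrix.to_frame().astype("object")
    for col in coded.columns:
        coded[col] = coded[col].map({1: "GOOD", 2: "MODERATE", 3: "POOR"})
    cumulative = profile_frame[
        profile_frame.interval_end - profile_frame.interval_start > 1]
    for (metric, s, e), sub in cumulative.groupby(
            ["metric", "interval_start", "interval_end"]):
        coded = coded.join(sub.set_index("patient_id")["category"]
                           .rename(f"{metric}_v{s}_v{e}"), how="left")
    assign_map = assignment.labels
    response_results = {}
    cat_rows = []
    for feature in coded.columns:
        table = cluster_stats.contingency_table(assign_map,
                                                coded[feature].to_dict())
        try:
            test = cluster_stats.chi_square_test(table)
        except ValueError:
            # feature constant across all patients: nothing to test
            logger.warning("skipping degenerate feature %s", feature)
            test = None
        if test is not None:
            response_results[feature] = test
        for cluster in table.counts.index:
            for category in table.counts.columns:
                cat_rows.append({
                    "feature": feature, "cluster": cluster, "category": category,
                    "count": int(table.counts.loc[cluster, category]),
                    "pct": round(float(table.row_pcts.loc[cluster, category]), 2),
                    "chi2": test.statistic if test else np.nan,
                    "df": test.df if test else 0,
                    "p": test.p_value if test else np.nan,
                })
    response_stats = pd.DataFrame(cat_rows)

    def is_categorical(col: str) -> bool:
        series = baselines[col]
        if series.dtype == object:
            return True
        values = set(series.dropna().unique())
        return values <= {0, 1}  # binary flags read back from CSV as ints

    feature_cols = [c for c in baselines.columns if c != "patient_id"]
    categorical = [c for c in feature_cols if is_categorical(c)]
    continuous = [c for c in feature_cols if c not in categorical]
    cont_summary, cat_summary = cluster_stats.cluster_summary(
        baselines, assign_map, continuous, categorical)
    baseline_results = {}
    for feature in continuous:
        baseline_results[feature] = cluster_stats.kruskal_wallis(
            assign_map, baselines.set_index("patient_id")[feature].to_dict())
    for feature in categorical:
        table = cluster_stats.contingency_table(
            assign_map, baselines.set_index("patient_id")[feature].to_dict())
        try:
            baseline_results[feature] = cluster_stats.chi_square_test(table)
        except ValueError:
            logger.warning("skipping degenerate baseline feature %s", feature)
    screen = cluster_stats.significance_screen(
        {**response_results, **baseline_results}, alpha=config.alpha)
    cont_summary["flag"] = cont_summary["p"] < config.alpha
    cont_summary.to_csv(out / "cluster_stats_continuous.csv", index=False)
    categorical_out = pd.concat([response_stats, cat_summary], ignore_index=True)
    categorical_out["flag"] = categorical_out["p"] < config.alpha
    categorical_out.to_csv(out / "cluster_stats_categorical.csv", index=False)
    screen.to_csv(out / "significance_screen.csv", index=False)

    # decision tree on baseline features, clustered patients only
    clustered = baselines[baselines["patient_id"].isin(assign_map)].copy()
    clustered = clustered.set_index("patient_id").loc[list(assign_map)].reset_index()
    design, onehot_parent = prepare_features(clustered)
    labels = [assign_map[pid] for pid in clustered["patient_id"]]
    root = fit_cart(design, labels, config.tree)
    importance = feature_importance(root, onehot_parent)
    predictions = predict(root, design)
    confusion = confusion_matrix(labels, predictions)
    (out / "tree.json").write_text(tree_to_json(root))
    (out / "tree.dot").write_text(tree_to_dot(root))
    importance.to_csv(out / "feature_importance.csv", index=False)
    confusion.to_csv(out / "tree_confusion.csv")

    manifest = {
        "seed": config.seed,
        "k": config.k,
        "advisory_k_by_gap": int(advisory_k),
        "alpha": config.alpha,
        "n_patients_input": int(len(visits)),
        "n_clustered": int(len(matrix.patient_ids)),
        "n_excluded": int(len(excluded)),
        "cluster_sizes": assignment.sizes(),
        "n_response_features": int(len(CLUSTERING_FEATURES)),
        "n_features_tested": int(len(response_results) + len(baseline_results)),
        "n_flagged": int(screen["flagged"].sum()) if len(screen) else 0,
        "training_accuracy": float((np.asarray(labels) == predictions).mean()),
        "config_digest": hashlib.sha256(
            yaml.safe_dump({
                "k": config.k, "alpha": config.alpha, "seed": config.seed,
                "rules": vars(config.rules), "tree": vars(config.tree),
            }, sort_keys=True).encode()).hexdigest()[:16],
    }
    (out / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=True))
    return {
        "profiles": profiles,
        "matrix": matrix,
        "excluded": excluded,
        "dendrogram": dendrogram,
        "assignment": assignment,
        "advisory_k": advisory_k,
        "response_stats": response_stats,
        "continuous_summary": cont_summary,
        "categorical_summary": cat_summary,
        "screen": screen,
        "tree": root,
        "importance": importance,
        "confusion": confusion,
        "manifest": manifest,
    }
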