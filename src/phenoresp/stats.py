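"""Cluster characterization: contingency tables, chi-square, Kruskal-Wallis.

Categorical features are compared across clusters with Pearson's chi-square
test of independence (no continuity correction, any table shape; cells with
expected count < 5 are flagged rather than silently switching tests).
Continuous features use the Kruskal-Wallis rank test with mid-rank tie
correction.  The significance screen flags raw p < alpha, matching the
study's unadjusted reporting; Benjamini-Hochberg q-values are emitted as an
extra column for transparency but do not drive the primary flags.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ContingencyTable",
    "StatTestResult",
    "contingency_table",
    "chi_square_test",
    "kruskal_wallis",
    "cluster_summary",
    "significance_screen",
]


@dataclass
class ContingencyTable:
    """Cluster-by-category counts with row percentages."""

    counts: pd.DataFrame  # rows = clusters, columns = categories
    row_pcts: pd.DataFrame

    @property
    def n(self) -> int:
        return int(self.counts.to_numpy().sum())


@dataclass
class StatTestResult:
    method: str  # "pearson_chi2" or "kruskal_wallis"
    statistic: float
    df: int
    p_value: float
    n_used: int
    warnings: list = field(default_factory=list)


def contingency_table(assignment: Mapping, feature: Mapping) -> ContingencyTable:
    """Cross-tabulate cluster labels against a categorical feature.

    Ids missing from either mapping, or with a missing feature value, are
    excluded pairwise.
    """
    ids = [i for i in assignment if i in feature and not pd.isna(feature[i])]
    if not ids:
        raise ValueError("no overlapping non-missing observations")
    clusters = pd.Series({i: assignment[i] for i in ids}, name="cluster")
    values = pd.Series({i: feature[i] for i in ids}, name="category")
    counts = pd.crosstab(clusters, values)
    totals = counts.sum(axis=1)
    pcts = counts.div(totals.where(totals > 0, np.nan), axis=0) * 100.0
    return ContingencyTable(counts=counts, row_pcts=pcts)


def chi_square_test(table: ContingencyTable) -> StatTestResult:
    """Pearson chi-square test of independence on a contingency table.

    All-zero rows or columns are dropped with a warning before testing; the
    statistic is the O/E summation without continuity correction, and the
    p-value comes from the chi-square upper tail with (r-1)(c-1) df.
    """
    counts = table.counts.to_numpy(dtype=float)
    notes = []
    row_keep = counts.sum(axis=1) > 0
    col_keep = counts.sum(axis=0) > 0
    if not row_keep.all() or not col_keep.all():
        notes.append("dropped all-zero row(s)/column(s)")
        counts = counts[np.ix_(row_keep, col_keep)]
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValueError("need at least a 2x2 table with positive margins")
    chi2, p, dof, expected = sps.chi2_contingency(counts, correction=False)
    if (expected < 5).any():
        notes.append("expected count < 5 in some cells")
    return StatTestResult(method="pearson_chi2", statistic=float(chi2),
                          df=int(dof), p_value=float(p),
                          n_used=int(counts.sum()), warnings=notes)


def kruskal_wallis(assignment: Mapping, feature: Mapping) -> StatTestResult:
    """Tie-corrected Kruskal-Wallis H test of a continuous feature.

    Clusters with zero non-missing observations are dropped with a warning;
    the p-value uses the chi-square approximation with k-1 df.
    """
    groups: dict = {}
    for pid, cluster in assignment.items():
        value = feature.get(pid)
        if value is None or (isinstance(value, float) and np.isnan(value)):
            continue
        groups.setdefault(cluster, []).append(float(value))
    notes = []
    nonempty = {c: v for c, v in groups.items() if v}
    if len(nonempty) < len(set(assignment.values())):
        notes.append("dropped empty cluster(s)")
    if len(nonempty) < 2:
        raise ValueError("need at least two clusters with observations")
    samples = [np.asarray(v) for _, v in sorted(nonempty.items())]
    if np.ptp(np.concatenate(samples)) == 0:
        # all observations identical: complete ties, H is 0 by definition
        stat, p = 0.0, 1.0
    else:
        stat, p = sps.kruskal(*samples)
    return StatTestResult(method="kruskal_wallis", statistic=float(stat),
                          df=len(samples) - 1, p_value=float(p),
                          n_used=int(sum(len(s) for s in samples)),
                          warnings=notes)


def cluster_summary(baselines: pd.DataFrame, assignment: Mapping,
                    continuous: Sequence[str], categorical: Sequence[str]
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cluster mean (SD) and N (%) report with per-feature tests.

    Returns ``(continuous_rows, categorical_rows)`` long-format frames, one
    row per (feature, cluster) or (feature, cluster, category), with the
    feature-level test statistic and p-value repeated on each row.
    Missing values are deleted pairwise per feature.
    """
    df = baselines.set_index("patient_id")
    clusters = pd.Series(assignment, name="cluster")
    df = df.join(clusters, how="inner")

    cont_rows = []
    for feature in continuous:
        test = kruskal_wallis(assignment, df[feature].to_dict())
        for cluster, sub in df.groupby("cluster")[feature]:
            vals = sub.dropna()
            cont_rows.append({
                "feature": feature, "cluster": cluster, "n": len(vals),
                "mean": vals.mean() if len(vals) else np.nan,
                "sd": vals.std(ddof=1) if len(vals) > 1 else 0.0,
                "H": test.statistic, "df": test.df, "p": test.p_value,
            })
    cat_rows = []
    for feature in categorical:
        table = contingency_table(assignment, df[feature].to_dict())
        try:
            test = chi_square_test(table)
        except ValueError:  # single observed category: nothing to test
            test = None
        for cluster in table.counts.index:
            for category in table.counts.columns:
                cat_rows.append({
                    "feature": feature, "cluster": cluster, "category": category,
                    "count": int(table.counts.loc[cluster, category]),
                    "pct": float(table.row_pcts.loc[cluster, category]),
                    "chi2": test.statistic if test else np.nan,
                    "df": test.df if test else 0,
                    "p": test.p_value if test else np.nan,
                    "expected_lt5": bool(
                        test and "expected count < 5 in some cells" in test.warnings),
                })
    return pd.DataFrame(cont_rows), pd.DataFrame(cat_rows)


def significance_screen(results: Mapping[str, StatTestResult],
                        alpha: float = 0.05) -> pd.DataFrame:
    """Flag features with raw p < alpha; BH q-values reported alongside.

    Returns a frame sorted by p with columns feature, method, statistic, df,
    p, q_bh, flagged.  Strict inequality: p exactly equal to alpha is not
    flagged.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if not results:
        return pd.DataFrame(columns=["feature", "method", "statistic", "df",
                                     "p", "q_bh", "flagged"])
    features = list(results)
    pvals = np.array([results[f].p_value for f in features])
    q = multipletests(pvals, method="fdr_bh")[1]
    out = pd.DataFrame({
        "feature": features,
        "method": [results[f].method for f in features],
        "statistic": [results[f].statistic for f in features],
        "df": [results[f].df for f in features],
        "p": pvals,
        "q_bh": q,
        "flagged": pvals < alpha,
    })
    return out.sort_values("p", kind="stable").reset_index(drop=True)
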