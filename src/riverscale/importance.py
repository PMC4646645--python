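"""Variable-importance pooling and group-level tests.

Per-variable relative influences from the final boosted-tree models are
pooled into the six hydromorphological variable groups (TOPO, PROFILE, BED,
BANK, LONG, FLOODPLAIN).  Selection counts are standardised to a frequency
per model and variable (SSF) so groups of different size are comparable.
Group differences are tested with a Kruskal-Wallis test followed by
pairwise Wilcoxon rank-sum tests with Bonferroni correction, and the trend
of a group's mean contribution across the five distance classes is measured
with a Spearman rank correlation (t statistic on 3 degrees of freedom).
"""

from __future__ import annotations

import itertools
import logging
import math

import numpy as np
import pandas as pd
from scipy import stats

from .catalog import Catalog

log = logging.getLogger(__name__)

__all__ = ["ssf", "group_contribution_stats", "group_tests", "kruskal_groups", "spearman_trend"]


def ssf(n_selected: int, n_models: int, n_group_vars: int) -> float:
    """Standardised selection frequency: selections per model and variable.

    Summaries truncate to 2 decimals (report convention); the returned value
    is exact.
    """
    if n_selected < 0 or n_models < 0 or n_group_vars < 0:
        raise ValueError("counts must be non-negative")
    if n_models * n_group_vars == 0:
        raise ZeroDivisionError("n_models * n_group_vars must be positive")
    return n_selected / (n_models * n_group_vars)


def format_ssf(value: float) -> str:
    """Truncate an SSF to 2 decimals for report parity."""
    return f"{math.floor(value * 100) / 100:.2f}"


def group_contribution_stats(fits, catalog: Catalog, meta: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-model summed contribution of each variable group.

    Every converged fit contributes one row per group (zero if none of the
    group's variables was selected), so per-model group sums total 100.
    Returns a long table ``model_id, species, group, contribution``; if
    ``meta`` (indexed by model id, e.g. varset/distance_m/topo factor
    levels) is given its columns are joined on.
    """
    groups = ["TOPO", "PROFILE", "BED", "BANK", "LONG", "FLOODPLAIN"]
    rows = []
    for fit in fits:
        if not fit.converged:
            continue
        sums = dict.fromkeys(groups, 0.0)
        for code, pct in fit.relative_influence.items():
            sums[catalog.group_of(code)] += pct
        for g in groups:
            rows.append((fit.dataset_id, fit.species, g, sums[g]))
    out = pd.DataFrame(rows, columns=["model_id", "species", "group", "contribution"])
    if meta is not None:
        out = out.join(meta, on="model_id")
    return out


def kruskal_groups(values_by_group: dict[str, np.ndarray]):
    """Kruskal-Wallis test over groups; returns (chi2, df, p)."""
    samples = [np.asarray(v, dtype=float) for v in values_by_group.values()]
    if len(samples) < 2 or any(len(s) < 2 for s in samples):
        raise ValueError("need >= 2 groups with >= 2 observations")
    stat, p = stats.kruskal(*samples)
    return float(stat), len(samples) - 1, float(p)


def pairwise_wilcoxon(values_by_group: dict[str, np.ndarray], exact: bool = False) -> pd.DataFrame:
    """Pairwise two-sided Wilcoxon rank-sum tests, Bonferroni adjusted."""
    names = list(values_by_group)
    pairs = list(itertools.combinations(names, 2))
    m = len(pairs)
    out = pd.DataFrame(np.nan, index=names, columns=names)
    for a, b in pairs:
        method = "exact" if exact else "asymptotic"
        res = stats.mannwhitneyu(
            values_by_group[a], values_by_group[b], alternative="two-sided", method=method
        )
        p = min(1.0, float(res.pvalue) * m)
        out.loc[a, b] = out.loc[b, a] = p
    return out


def spearman_trend(mean_by_distance: pd.Series):
    """Spearman correlation of group means against the ordered distance
    classes, with the t statistic on n - 2 (here 3) degrees of freedom."""
    y = mean_by_distance.sort_index()
    n = len(y)
    if n < 3:
        raise ValueError("need at least 3 distance classes")
    r, _ = stats.spearmanr(np.arange(n), y.to_numpy())
    if abs(r) > 1.0 - 1e-12:
        r = math.copysign(1.0, r)
    if abs(r) >= 1.0:
        t = math.inf if r > 0 else -math.inf
        p = 0.0
    else:
        t = r * math.sqrt((n - 2) / (1 - r * r))
        p = 2 * stats.t.sf(abs(t), n - 2)
    return float(r), float(t), n - 2, float(p)


def group_tests(table: pd.DataFrame, distance_col: str | None = None, exact: bool = False) -> dict:
    """Run the group-difference and trend tests on a contribution table.

    ``table`` needs ``group`` and ``contribution`` columns; if
    ``distance_col`` is given, per-group Spearman trends of the mean
    contribution across distance classes are added.  Constant data skip the
    rank tests with a warning.
    """
    values = {g: grp["contribution"].to_numpy() for g, grp in table.groupby("group")}
    report: dict = {}
    if np.ptp(table["contribution"].to_numpy()) == 0:
        log.warning("group_tests: constant contributions; rank tests skipped")
        report["kruskal"] = None
        report["pairwise"] = None
    else:
        report["kruskal"] = kruskal_groups(values)
        report["pairwise"] = pairwise_wilcoxon(values, exact=exact)
    if distance_col is not None:
        trends = {}
        for g, grp in table.groupby("group"):
            means = grp.groupby(distance_col)["contribution"].mean()
            if means.nunique() <= 1:
                continue
            trends[g] = spearman_trend(means)
        report["trends"] = trends
    return report
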