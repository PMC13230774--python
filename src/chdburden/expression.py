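"""Bulk developmental-expression profiling of gene sets.

Works from a long-format RPKM table (gene_id, tissue, stage, rpkm) over
the four tissues heart / kidney / brain / liver across developmental
stages in weeks post conception.  The profile of interest is the mean
expression in the early window (4-8 wpc, inclusive), converted to
per-tissue percentile ranks, on which two gene sets (e.g. syndromic vs
non-syndromic CHD genes) are compared per tissue by a two-sided Wilcoxon
rank-sum test with Bonferroni correction over tissues.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, rankdata

TISSUES = ("heart", "kidney", "brain", "liver")


def validate_expression(expr: pd.DataFrame) -> pd.DataFrame:
    for col in ("gene_id", "tissue", "stage", "rpkm"):
        if col not in expr.columns:
            raise ValueError(f"expression table missing column {col!r}")
    if (expr["rpkm"] < 0).any():
        raise ValueError("RPKM values must be non-negative")
    if expr["tissue"].isna().any() or expr["stage"].isna().any():
        raise ValueError("every sample needs a tissue and a stage")
    return expr


def mean_early_expression(expr: pd.DataFrame,
                          stage_window=(4.0, 8.0)) -> pd.DataFrame:
    """Per-gene mean RPKM per tissue over the early window (inclusive).

    Returns a genes x tissues DataFrame.  A tissue with no sample inside
    the window is omitted with a warning.
    """
    validate_expression(expr)
    lo, hi = stage_window
    inside = expr[(expr["stage"] >= lo) & (expr["stage"] <= hi)]
    present = set(inside["tissue"])
    for tissue in sorted(set(expr["tissue"]) - present):
        warnings.warn(f"tissue {tissue!r} has no sample in the "
                      f"{lo}-{hi} wpc window; omitted", stacklevel=2)
    means = inside.pivot_table(index="gene_id", columns="tissue",
                               values="rpkm", aggfunc="mean")
    means.columns.name = None
    return means


def percentile_rank(values) -> pd.Series:
    """Midrank percentile: 100 * (rank - 0.5) / n, ties share the midrank.

    Invariant under strictly monotone transforms of the input.
    """
    s = pd.Series(values, dtype=float)
    if s.empty:
        raise ValueError("empty vector")
    ranks = rankdata(s.to_numpy(), method="average")
    return pd.Series(100.0 * (ranks - 0.5) / len(s), index=s.index)


def percentile_table(means: pd.DataFrame) -> pd.DataFrame:
    """Per-tissue percentile ranks of the per-gene mean expression."""
    return means.apply(percentile_rank, axis=0)


def compare_gene_sets(percentiles: pd.DataFrame, set_a, set_b,
                      tissues=None, exact_max_n: int = 20) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum of set A vs set B per tissue.

    Run on percentile values; exact null for combined n <= ``exact_max_n``,
    normal approximation with continuity correction otherwise.  Bonferroni
    factor = number of tissues tested.  Symmetric in (set_a, set_b).
    """
    tissues = list(tissues) if tissues is not None else list(percentiles.columns)
    idx = percentiles.index
    a = [g for g in set_a if g in idx]
    b = [g for g in set_b if g in idx]
    if not a:
        raise ValueError("set_a has no gene present in the expression matrix")
    if not b:
        raise ValueError("set_b has no gene present in the expression matrix")

    rows = []
    for tissue in tissues:
        xa = percentiles.loc[a, tissue].dropna().to_numpy()
        xb = percentiles.loc[b, tissue].dropna().to_numpy()
        pooled = np.concatenate([xa, xb])
        has_ties = np.unique(pooled).size < pooled.size
        # scipy's exact null assumes no ties; fall back when they occur
        method = ("exact" if len(pooled) <= exact_max_n and not has_ties
                  else "asymptotic")
        stat, p = mannwhitneyu(xa, xb, alternative="two-sided", method=method)
        rows.append({"tissue": tissue, "n_a": len(xa), "n_b": len(xb),
                     "median_a": float(np.median(xa)),
                     "median_b": float(np.median(xb)),
                     "u_statistic": float(stat), "p": float(p),
                     "p_bonferroni": float(min(1.0, p * len(tissues)))})
    return pd.DataFrame(rows)
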