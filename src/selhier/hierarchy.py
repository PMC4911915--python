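"""Descriptive statistics of the selenium dose-response hierarchy.

Operations on a replicate-level :class:`~selhier.datasets.ExpressionDataset`:
normalization to the no-added-selenium (NoSe) reference, the 40 nM/NoSe
hierarchy ratio per gene, the signed decomposition of the total abundance
change into per-gene contributions, and the Spearman rank correlation between
mRNA abundance (at 10 nM selenite) and position in the hierarchy (the
40 nM/NoSe ratio) — with an exact permutation p-value for small panels.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datasets import ExpressionDataset

__all__ = [
    "HierarchyError",
    "normalize_to_reference",
    "hierarchy_table",
    "total_change_contributions",
    "spearman_hierarchy_correlation",
    "exact_spearman_pvalue",
]

#: Largest panel for which the permutation p-value is computed exhaustively.
EXACT_PERMUTATION_MAX_N = 10


class HierarchyError(ValueError):
    pass


def _condition_means(ds: ExpressionDataset) -> pd.DataFrame:
    """Per gene x condition mean of the raw abundance, wide format."""
    return (
        ds.df.groupby(["gene_id", "selenite_nM"])["abundance"]
        .mean()
        .unstack("selenite_nM")
    )


def normalize_to_reference(ds: ExpressionDataset, reference: float = 0.0) -> ExpressionDataset:
    """Divide each gene's abundances by its mean at the reference condition.

    The returned dataset carries the result in the ``normalized`` column; the
    raw abundances are kept.  Idempotent on already-normalized data (the
    reference mean of a normalized gene is 1).
    """
    df = ds.df.copy()
    ref = df[df["selenite_nM"] == reference]
    if ref.empty:
        raise HierarchyError(f"reference condition {reference} nM absent from dataset")
    ref_means = ref.groupby("gene_id")["abundance"].mean()
    missing = set(df["gene_id"]) - set(ref_means.index)
    if missing:
        raise HierarchyError(f"gene(s) {sorted(missing)} lack the reference condition")
    df["normalized"] = df["abundance"] / df["gene_id"].map(ref_means)
    return ExpressionDataset(df)


def total_change_contributions(
    ds: ExpressionDataset, high: float = 40.0, low: float = 0.0
) -> pd.Series:
    """Signed share of each gene in the total abundance change high vs low.

    Shares are computed on the raw (un-normalized) condition means,
    ``(mean_g(high) - mean_g(low)) / sum_g(...)``; they sum to 1 and genes that
    decrease get negative shares.  Invariant to rescaling all abundances by a
    common factor.
    """
    means = _condition_means(ds)
    for c in (high, low):
        if c not in means.columns:
            raise HierarchyError(f"condition {c} nM absent from dataset")
    delta = means[high] - means[low]
    total = delta.sum()
    if total == 0:
        raise HierarchyError("total change between conditions is zero; shares undefined")
    return (delta / total).rename("contribution_share")


def hierarchy_table(
    ds: ExpressionDataset,
    high: float = 40.0,
    low: float = 0.0,
    abundance_at: float = 10.0,
) -> pd.DataFrame:
    """Per-gene hierarchy summary: condition means, NoSe-normalized means,
    the high/low ratio, contribution shares, and the two rankings (rank 1 =
    most abundant / largest ratio)."""
    means = _condition_means(ds)
    for c in (high, low, abundance_at):
        if c not in means.columns:
            raise HierarchyError(f"condition {c} nM absent from dataset")
    out = means.copy()
    out.columns = [f"mean_{c:g}nM" for c in means.columns]
    for c in means.columns:
        out[f"norm_{c:g}nM"] = means[c] / means[low]
    out["ratio_high_low"] = means[high] / means[low]
    out["contribution_share"] = total_change_contributions(ds, high, low)
    out["abundance_rank"] = means[abundance_at].rank(ascending=False, method="average")
    out["hierarchy_rank"] = out["ratio_high_low"].rank(ascending=False, method="average")
    return out.reset_index()


def exact_spearman_pvalue(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided permutation p-value of Spearman's rho by full enumeration.

    Permutes the assignment of one rank vector against the other over all n!
    orderings (mid-ranks for ties, so the null distribution conditions on the
    observed tie pattern).  Feasible for n <= 10.
    """
    n = len(x)
    if n != len(y) or n < 3:
        raise HierarchyError("need two equal-length vectors with n >= 3")
    if n > EXACT_PERMUTATION_MAX_N:
        raise HierarchyError(f"exact enumeration limited to n <= {EXACT_PERMUTATION_MAX_N}")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rx_c = rx - rx.mean()
    ry_c = ry - ry.mean()
    denom = math.sqrt(float(rx_c @ rx_c) * float(ry_c @ ry_c))
    if denom == 0:
        raise HierarchyError("a rank vector is constant; rho undefined")
    observed = abs(float(rx_c @ ry_c) / denom)
    perms = np.array(list(itertools.permutations(range(n))), dtype=np.int16)
    rho_all = np.abs(ry_c[perms] @ rx_c) / denom
    hits = int(np.sum(rho_all >= observed - 1e-12))
    return hits / math.factorial(n)


def spearman_hierarchy_correlation(
    ds: ExpressionDataset,
    abundance_at: float = 10.0,
    ratio_high: float = 40.0,
    ratio_low: float = 0.0,
) -> tuple[float, float]:
    """Spearman rho between abundance ranking and hierarchy ranking.

    Abundance ranking: raw mean abundance at ``abundance_at`` nM.  Hierarchy
    ranking: the ``ratio_high/ratio_low`` dose-response ratio.  The p-value is
    the exact permutation probability for panels of up to 10 genes and the
    asymptotic approximation above that.
    """
    means = _condition_means(ds)
    for c in (abundance_at, ratio_high, ratio_low):
        if c not in means.columns:
            raise HierarchyError(f"condition {c} nM absent from dataset")
    if len(means) < 3:
        raise HierarchyError("need at least 3 genes for a rank correlation")
    x = means[abundance_at].to_numpy(float)
    y = (means[ratio_high] / means[ratio_low]).to_numpy(float)
    rho = float(sps.spearmanr(x, y).statistic)
    if len(x) <= EXACT_PERMUTATION_MAX_N:
        p = exact_spearman_pvalue(x, y)
    else:
        p = float(sps.spearmanr(x, y).pvalue)
    return rho, p
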