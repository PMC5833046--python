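"""Tie-corrected Kruskal-Wallis test and Dunn's post-hoc, from formulas.

Both tests are implemented directly from their rank formulas (rather than
delegated to a library) because they are the statistical core of the
pipeline; library implementations serve as independent oracles in the
test suite.

Kruskal-Wallis with mid-ranks over the pooled sample of size N in g
groups with rank sums R_j:

    H = [ 12 / (N (N+1)) * sum_j R_j^2 / n_j - 3 (N+1) ] / C
    C = 1 - sum_ties (t^3 - t) / (N^3 - N)

and p from chi-square with g - 1 degrees of freedom (the approximation
the original analysis software uses).  When every pooled value is
identical the statistic is defined as H = 0, p = 1.  An exact permutation
mode enumerates all distinct group assignments for small samples.

Dunn's z for group j against the control c:

    z = (Rbar_c - Rbar_j) / sqrt( [ N(N+1)/12 - sum(t^3 - t)/(12 (N-1)) ]
                                   * (1/n_c + 1/n_j) )

with two-sided normal p-values, Bonferroni-adjusted over the
versus-control comparisons (raw p always reported alongside).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "KWResult",
    "kruskal_wallis",
    "kruskal_wallis_matrix",
    "dunn_posthoc",
    "flag_significant",
    "p_stars",
    "group_test_table",
]

ALPHA = 0.05


@dataclass(frozen=True)
class KWResult:
    h: float
    df: int
    p: float


def _tie_term(ranks_or_values: np.ndarray) -> float:
    """``sum(t^3 - t)`` over tie groups of the pooled sample."""
    _, counts = np.unique(ranks_or_values, return_counts=True)
    t = counts.astype(float)
    return float(np.sum(t**3 - t))


def _h_statistic(values: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    n = values.size
    ranks = stats.rankdata(values)
    rank_sums = np.bincount(codes, weights=ranks, minlength=n_groups)
    sizes = np.bincount(codes, minlength=n_groups)
    h = 12.0 / (n * (n + 1)) * np.sum(rank_sums**2 / sizes) - 3.0 * (n + 1)
    correction = 1.0 - _tie_term(values) / (n**3 - n)
    if correction <= 0:  # all pooled values identical
        return 0.0
    return float(h / correction)


def _encode_groups(groups: Sequence) -> tuple[np.ndarray, list]:
    labels = list(dict.fromkeys(groups))  # preserve first-appearance order
    mapping = {g: i for i, g in enumerate(labels)}
    return np.array([mapping[g] for g in groups]), labels


def kruskal_wallis(
    values: Sequence[float],
    groups: Sequence,
    method: str = "chi2",
    max_exact: int = 200_000,
) -> KWResult:
    """Tie-corrected Kruskal-Wallis test.

    ``method="chi2"`` uses the chi-square approximation with
    ``df = g - 1``; ``method="exact"`` enumerates all distinct label
    arrangements (suitable for total N up to about 12) and returns
    ``P(H_perm >= H_obs)``.
    """
    values = np.asarray(values, dtype=float)
    codes, labels = _encode_groups(groups)
    if len(labels) < 2:
        raise ValueError("kruskal_wallis needs at least two groups")
    if values.size != codes.size:
        raise ValueError("values and groups differ in length")
    if np.bincount(codes).min() < 1:
        raise ValueError("every group needs at least one observation")
    df = len(labels) - 1
    h = _h_statistic(values, codes, len(labels))
    if np.ptp(values) == 0:
        return KWResult(h=0.0, df=df, p=1.0)
    if method == "chi2":
        p = float(stats.chi2.sf(h, df))
    elif method == "exact":
        p = _exact_p(values, codes, len(labels), h, max_exact)
    else:
        raise ValueError(f"unknown method {method!r}")
    return KWResult(h=h, df=df, p=min(p, 1.0))


def _exact_p(values: np.ndarray, codes: np.ndarray, n_groups: int,
             h_obs: float, max_exact: int) -> float:
    """Full enumeration of distinct group assignments of the ranks."""
    n = values.size
    sizes = np.bincount(codes, minlength=n_groups)
    ranks = stats.rankdata(values)
    count = total = 0
    indices = list(range(n))

    def recurse(remaining: tuple[int, ...], sums: list[float], g: int) -> None:
        nonlocal count, total
        if g == n_groups - 1:
            last = sum(ranks[i] for i in remaining)
            all_sums = sums + [last]
            n_ = n
            h = 12.0 / (n_ * (n_ + 1)) * sum(
                s * s / sz for s, sz in zip(all_sums, sizes)) - 3.0 * (n_ + 1)
            corr = 1.0 - _tie_term(values) / (n_**3 - n_)
            h = h / corr if corr > 0 else 0.0
            total += 1
            if h >= h_obs - 1e-12:
                count += 1
            return
        for combo in combinations(remaining, sizes[g]):
            rest = tuple(i for i in remaining if i not in set(combo))
            recurse(rest, sums + [sum(ranks[i] for i in combo)], g + 1)

    # guard against combinatorial blow-up
    from math import comb
    arrangements = 1
    left = n
    for sz in sizes:
        arrangements *= comb(left, int(sz))
        left -= int(sz)
    if arrangements > max_exact:
        raise ValueError(
            f"exact enumeration of {arrangements} arrangements exceeds "
            f"max_exact={max_exact}; use method='chi2'")
    recurse(tuple(indices), [], 0)
    return count / total


def kruskal_wallis_matrix(
    matrix: np.ndarray | pd.DataFrame, groups: Sequence
) -> pd.DataFrame:
    """Vectorized KW over many genes (rows) sharing one group layout."""
    if isinstance(matrix, pd.DataFrame):
        index = matrix.index
        values = matrix.to_numpy(dtype=float)
    else:
        values = np.asarray(matrix, dtype=float)
        index = pd.RangeIndex(values.shape[0])
    codes, labels = _encode_groups(groups)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    n = values.shape[1]
    sizes = np.bincount(codes, minlength=len(labels))
    ranks = stats.rankdata(values, axis=1)
    indicator = np.zeros((n, len(labels)))
    indicator[np.arange(n), codes] = 1.0
    rank_sums = ranks @ indicator
    h = 12.0 / (n * (n + 1)) * (rank_sums**2 / sizes).sum(axis=1) - 3.0 * (n + 1)
    ties = np.array([_tie_term(row) for row in values])
    correction = 1.0 - ties / (n**3 - n)
    h = np.where(correction > 0, h / np.where(correction > 0, correction, 1.0), 0.0)
    df = len(labels) - 1
    p = stats.chi2.sf(h, df)
    p = np.where(correction > 0, p, 1.0)
    return pd.DataFrame({"h": h, "df": df, "p": p}, index=index)


# ---------------------------------------------------------------------------
# Dunn's multiple-comparison post-hoc (each group vs the control)
# ---------------------------------------------------------------------------

def dunn_posthoc(
    values: Sequence[float],
    groups: Sequence,
    control: str = "term",
    adjust: str = "bonferroni",
) -> pd.DataFrame:
    """Dunn's z for every non-control group against the control.

    Mid-ranks over the pooled sample; the tie-corrected variance term is
    ``N(N+1)/12 - sum(t^3 - t) / (12 (N-1))``.  ``p_adj`` multiplies the
    two-sided normal p by the number of comparisons (capped at 1).
    """
    values = np.asarray(values, dtype=float)
    codes, labels = _encode_groups(groups)
    if control not in labels:
        raise ValueError(f"control group {control!r} empty or absent")
    n = values.size
    ranks = stats.rankdata(values)
    sizes = np.bincount(codes, minlength=len(labels))
    mean_ranks = np.bincount(codes, weights=ranks, minlength=len(labels)) / sizes
    variance = n * (n + 1) / 12.0 - _tie_term(values) / (12.0 * (n - 1))
    c = labels.index(control)
    others = [g for g in labels if g != control]
    rows = []
    for g in others:
        j = labels.index(g)
        se = np.sqrt(variance * (1.0 / sizes[c] + 1.0 / sizes[j]))
        z = (mean_ranks[c] - mean_ranks[j]) / se if se > 0 else 0.0
        p_raw = 2.0 * stats.norm.sf(abs(z)) if se > 0 else 1.0
        rows.append({"comparison": f"{g} vs {control}", "group": g,
                     "z": z, "p_raw": min(p_raw, 1.0)})
    out = pd.DataFrame(rows)
    if adjust == "bonferroni":
        out["p_adj"] = np.minimum(1.0, out["p_raw"] * len(others))
    elif adjust == "none":
        out["p_adj"] = out["p_raw"]
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    return out


# ---------------------------------------------------------------------------
# Per-gene orchestration
# ---------------------------------------------------------------------------

def flag_significant(results: pd.DataFrame, alpha: float = ALPHA) -> set[str]:
    """Genes with KW p strictly below alpha (p = alpha is not significant)."""
    if results.empty:
        return set()
    return set(results.index[results["p"] < alpha])


def p_stars(p: float) -> str:
    """Significance bands: *** < 0.001, ** < 0.01, * < 0.05, else ns."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def group_test_table(
    fc: pd.DataFrame,
    control: str = "term",
    alpha: float = ALPHA,
    value_col: str = "log2_fc",
) -> pd.DataFrame:
    """KW + Dunn per gene on a long-format per-sample fold-change table.

    Returns one row per gene: H, df, p, stars, significance flag and, per
    non-control group, the Dunn z / raw p / adjusted p columns.  The test
    is rank-based, so running it on log2 FC, linear FC or raw dCt gives
    identical H and p (monotone invariance; dCt flips every sign of z).
    """
    rows = []
    for gene, sub in fc.groupby("gene", sort=True):
        values = sub[value_col].to_numpy(dtype=float)
        groups = sub["group"].tolist()
        kw = kruskal_wallis(values, groups)
        row: dict[str, object] = {
            "gene": gene, "h": kw.h, "df": kw.df, "p": kw.p,
            "stars": p_stars(kw.p), "significant": kw.p < alpha,
        }
        dunn = dunn_posthoc(values, groups, control=control)
        for _, cmp_row in dunn.iterrows():
            g = cmp_row["group"]
            row[f"dunn_z[{g}]"] = cmp_row["z"]
            row[f"dunn_p_raw[{g}]"] = cmp_row["p_raw"]
            row[f"dunn_p_adj[{g}]"] = cmp_row["p_adj"]
        rows.append(row)
    return pd.DataFrame(rows).set_index("gene")
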