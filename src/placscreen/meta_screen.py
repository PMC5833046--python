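"""Per-study differential-expression screening and cross-study candidate
selection.

The screen runs on log2 expression matrices, one study at a time:

1. quantile normalization equalizes the per-sample value distributions;
2. a moderated two-sample t-statistic contrasts a disease arm against the
   study's controls, with empirical-Bayes variance shrinkage
   ``s~_g^2 = (d0*s0^2 + dg*s_g^2) / (d0 + dg)`` whose prior ``(d0, s0^2)``
   is fitted by the method of moments on the log sample variances;
3. genes are ranked per contrast by log2 fold change (top-k up and down);
4. a gene becomes a candidate when it is measured in at least
   ``min_studies`` studies, reaches a top-k list of at least one contrast,
   and carries a curated placenta-relevance flag (the flag is an input,
   not computed).

The moments fit follows the classic scaled-inverse-chi-square hierarchy:
with ``z_g = log s_g^2``, ``E z_g = log s0^2 + psi(dg/2) - log(dg/2)
- (psi(d0/2) - log(d0/2))`` and ``Var z_g = psi'(dg/2) + psi'(d0/2)``, so
``d0`` solves a trigamma equation (Newton iteration) and ``s0^2`` follows
from the mean.  When the excess variance of ``z_g`` is non-positive the
moment estimate diverges and ``d0`` is capped at ``D0_CAP``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from .tabular_io import ExpressionStudy, TableFormatError

__all__ = [
    "D0_CAP",
    "DEResult",
    "CandidateSet",
    "quantile_normalize",
    "fit_variance_prior",
    "moderated_t",
    "de_statistics",
    "rank_top_k",
    "select_candidates",
]

D0_CAP = 50.0


# ---------------------------------------------------------------------------
# Quantile normalization
# ---------------------------------------------------------------------------

def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every column onto the common distribution of row-wise means.

    The reference distribution is the row-wise mean of the per-column
    sorted values; each column's entries are replaced by the reference
    value at their rank, ties receiving the mean of the reference values
    their rank span covers.  Idempotent; a single-column matrix is
    returned unchanged with a warning.
    """
    if matrix.isna().any().any():
        raise ValueError("quantile_normalize requires a complete matrix")
    if matrix.shape[1] < 2:
        warnings.warn("quantile_normalize: single-column input returned "
                      "unchanged", UserWarning, stacklevel=2)
        return matrix.copy()
    values = matrix.to_numpy(dtype=float)
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        col = values[:, j]
        order = np.argsort(col, kind="mergesort")
        assigned = np.empty_like(col)
        assigned[order] = reference
        # ties: average the reference values spanned by each tied block
        sorted_col = col[order]
        block_start = 0
        for i in range(1, len(col) + 1):
            if i == len(col) or sorted_col[i] != sorted_col[block_start]:
                if i - block_start > 1:
                    assigned[order[block_start:i]] = reference[block_start:i].mean()
                block_start = i
        out[:, j] = assigned
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


# ---------------------------------------------------------------------------
# Moderated t
# ---------------------------------------------------------------------------

def fit_variance_prior(s2: np.ndarray, dg: float) -> tuple[float, float]:
    """Method-of-moments fit of the variance prior ``(d0, s0^2)``.

    ``s2`` are per-gene pooled sample variances with ``dg`` residual
    degrees of freedom each.  Genes with zero variance are excluded from
    the fit.  Returns ``(d0, s0_sq)`` with ``d0`` capped at :data:`D0_CAP`
    when the moment estimate is non-positive or infinite.
    """
    s2 = np.asarray(s2, dtype=float)
    positive = s2[s2 > 0]
    if positive.size < 2:
        return D0_CAP, float(positive.mean()) if positive.size else 1.0
    z = np.log(positive)
    e = z - special.digamma(dg / 2.0) + np.log(dg / 2.0)
    e_mean = e.mean()
    excess = e.var(ddof=1) - special.polygamma(1, dg / 2.0)
    if not np.isfinite(excess) or excess <= 0:
        d0 = D0_CAP
    else:
        d0 = 2.0 * _trigamma_inverse(excess)
        if not np.isfinite(d0) or d0 <= 0 or d0 > 1e8:
            d0 = D0_CAP
    s0_sq = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return float(d0), s0_sq


def _trigamma_inverse(x: float) -> float:
    """Solve ``psi'(y) = x`` for ``y > 0`` by Newton iteration."""
    if x <= 0:
        return np.inf
    y = 0.5 + 1.0 / x  # standard starting value
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def moderated_t(
    log2_fc: np.ndarray,
    s2: np.ndarray,
    n1: int,
    n2: int,
    d0: float,
    s0_sq: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Moderated t, its degrees of freedom and two-sided p-values.

    ``s2`` is the pooled two-sample variance per gene with
    ``dg = n1 + n2 - 2`` degrees of freedom; the shrunken variance is the
    precision-weighted blend of ``s2`` with the prior ``s0_sq``.
    """
    dg = n1 + n2 - 2
    s2_tilde = (d0 * s0_sq + dg * np.asarray(s2, dtype=float)) / (d0 + dg)
    se = np.sqrt(s2_tilde * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, np.asarray(log2_fc) / np.where(se > 0, se, 1.0), 0.0)
    df = dg + d0
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return t, np.full_like(t, df, dtype=float), np.minimum(p, 1.0)


@dataclass
class DEResult:
    """Per-gene differential-expression result for one study contrast."""

    study_id: str
    contrast: str
    table: pd.DataFrame  # index gene; log2_fc, t, df, p, rank_up, rank_down
    d0: float
    s0_sq: float


def de_statistics(study: ExpressionStudy, contrast: str,
                  control_group: str = "control") -> DEResult:
    """Moderated-t differential expression of ``contrast`` vs controls.

    log2 FC is disease mean minus control mean per gene.  Ranks are
    1-based and unique per direction: by largest (``rank_up``) or smallest
    (``rank_down``) FC, ties broken by smaller p then gene id.
    """
    disease = study.samples_in_group(contrast)
    controls = study.samples_in_group(control_group)
    if not disease:
        raise TableFormatError(
            f"study {study.study_id!r}: contrast group {contrast!r} absent")
    if len(disease) < 2 or len(controls) < 2:
        raise TableFormatError(
            f"study {study.study_id!r}: need >= 2 samples per group for "
            f"{contrast!r} vs {control_group!r}")
    x = study.matrix[disease].to_numpy(dtype=float)
    c = study.matrix[controls].to_numpy(dtype=float)
    n1, n2 = x.shape[1], c.shape[1]
    fc = x.mean(axis=1) - c.mean(axis=1)
    dg = n1 + n2 - 2
    s2 = ((x.var(axis=1, ddof=1) * (n1 - 1)) + (c.var(axis=1, ddof=1) * (n2 - 1))) / dg
    d0, s0_sq = fit_variance_prior(s2, dg)
    t, df, p = moderated_t(fc, s2, n1, n2, d0, s0_sq)

    table = pd.DataFrame(
        {"log2_fc": fc, "t": t, "df": df, "p": p},
        index=pd.Index(study.genes, name="gene"),
    )
    # identical group means: define t = 0, p = 1 exactly
    zero = fc == 0
    table.loc[zero, "t"] = 0.0
    table.loc[zero, "p"] = 1.0

    up = table.iloc[np.lexsort((table.index, table["p"], -table["log2_fc"]))]
    table["rank_up"] = pd.Series(np.arange(1, len(up) + 1), index=up.index)
    down = table.iloc[np.lexsort((table.index, table["p"], table["log2_fc"]))]
    table["rank_down"] = pd.Series(np.arange(1, len(down) + 1), index=down.index)
    return DEResult(study.study_id, contrast, table, d0, s0_sq)


def rank_top_k(de: DEResult, k: int = 12) -> tuple[list[str], list[str]]:
    """Top-k up- and down-regulated gene lists of one contrast."""
    if k > len(de.table):
        raise ValueError(f"k={k} exceeds the {len(de.table)} genes measured")
    up = de.table.sort_values("rank_up").index[:k].tolist()
    down = de.table.sort_values("rank_down").index[:k].tolist()
    return up, down


# ---------------------------------------------------------------------------
# Cross-study candidate selection
# ---------------------------------------------------------------------------

@dataclass
class CandidateSet:
    """Vote-count selection result across studies."""

    table: pd.DataFrame  # per gene: n_studies, best ranks, flag, fc range, selected

    @property
    def selected(self) -> list[str]:
        return list(self.table.index[self.table["selected"]])


def select_candidates(
    results: Sequence[DEResult],
    annotations: Mapping[str, bool],
    min_studies: int = 4,
    k: int = 12,
) -> CandidateSet:
    """Apply the three-part candidate rule across study contrasts.

    A gene is selected iff (i) it is measured in at least ``min_studies``
    distinct studies (the strict reading of "more than 3"), (ii) it
    appears in the top-k up or down list of at least one study contrast,
    and (iii) its curated annotation flag is true.  The cross-study log2
    FC range is reported per gene as ``min~max``.
    """
    if not results:
        raise ValueError("select_candidates needs at least one DE result")
    genes: dict[str, dict] = {}
    studies_per_gene: dict[str, set[str]] = {}
    for de in results:
        up, down = rank_top_k(de, k=min(k, len(de.table)))
        top = set(up) | set(down)
        for gene, row in de.table.iterrows():
            rec = genes.setdefault(gene, {
                "best_rank_up": np.inf, "best_rank_down": np.inf,
                "in_top_k": False, "fc_min": np.inf, "fc_max": -np.inf,
            })
            studies_per_gene.setdefault(gene, set()).add(de.study_id)
            rec["best_rank_up"] = min(rec["best_rank_up"], row["rank_up"])
            rec["best_rank_down"] = min(rec["best_rank_down"], row["rank_down"])
            rec["in_top_k"] = rec["in_top_k"] or gene in top
            rec["fc_min"] = min(rec["fc_min"], row["log2_fc"])
            rec["fc_max"] = max(rec["fc_max"], row["log2_fc"])

    rows = []
    for gene in sorted(genes):
        rec = genes[gene]
        n_studies = len(studies_per_gene[gene])
        flag = bool(annotations.get(gene, False))
        selected = n_studies >= min_studies and rec["in_top_k"] and flag
        rows.append({
            "gene": gene,
            "n_studies": n_studies,
            "best_rank_up": int(rec["best_rank_up"]),
            "best_rank_down": int(rec["best_rank_down"]),
            "in_top_k": rec["in_top_k"],
            "placenta_annotated": flag,
            "log2_fc_min": rec["fc_min"],
            "log2_fc_max": rec["fc_max"],
            "log2_fc_range": f"{rec['fc_min']:.2f}~{rec['fc_max']:.2f}",
            "selected": selected,
        })
    table = pd.DataFrame(rows).set_index("gene")
    return CandidateSet(table=table)
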