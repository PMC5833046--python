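"""Dual-disease fold-change specificity calls ("mathematical diagramming").

Each gene is a point (x, y) where x is its average log2 fold change in
isolated IUGR and y in isolated PE, both against term controls.  Genes
whose expression moved by less than a linear fold change of 1.14 in both
diseases are filtered out; the remainder are classified by where the
point lies relative to the axes and the diagonals, with an error band of
``epsilon`` log2 units:

1. ``|y| <= eps < |x|``      -> IUGR_dominant  (the ratio r = y/x -> 0)
2. ``|x| <= eps < |y|``      -> PE_dominant    (|r| -> infinity)
3. ``|y - x| <= eps``        -> equal          (near the y = x line, r ~ 1)
4. ``|y + x| <= eps``        -> equal_reversed (near y = -x, r ~ -1)
5. otherwise                 -> mixed

The rules are evaluated in this fixed order so every retained point gets
exactly one class.  The ratio r = y/x is reported throughout as the rank
variable (signed infinity when x = 0).  The final targets are the
intersection of the statistically significant set with the top-ranked
dominant genes and the equal/equal_reversed classes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import pandas as pd

__all__ = [
    "FC_THRESHOLD",
    "EPSILON",
    "SpecificityCall",
    "fc_filter",
    "classify",
    "classify_table",
    "rank_dominant",
    "intersect_targets",
]

FC_THRESHOLD = 1.14  # linear fold change; log2(1.14) ~ 0.189 log2 units
EPSILON = 0.2        # error band, log2 units

CLASSES = ("IUGR_dominant", "PE_dominant", "equal", "equal_reversed",
           "mixed", "unclassified")


@dataclass(frozen=True)
class SpecificityCall:
    gene: str
    x: float
    y: float
    r: float          # rank variable y/x; signed inf when x == 0
    label: str        # one of CLASSES
    retained: bool    # passed the FC filter


def fc_filter(x: float, y: float, threshold: float = FC_THRESHOLD) -> bool:
    """Keep a gene iff its linear FC exceeds the threshold in >= 1 disease.

    On the log2 scale: ``max(|x|, |y|) > log2(threshold)`` (strict, so a
    fold change of exactly 1.14 in both diseases is excluded).
    """
    cut = math.log2(threshold)
    return max(abs(x), abs(y)) > cut


def _ratio(x: float, y: float) -> float:
    if x != 0.0:
        return y / x
    if y == 0.0:
        return math.nan
    return math.copysign(math.inf, y)


def classify(
    x: float,
    y: float,
    epsilon: float = EPSILON,
    threshold: float = FC_THRESHOLD,
) -> SpecificityCall:
    """Classify one (x, y) point; unretained points get ``unclassified``."""
    r = _ratio(x, y)
    if not fc_filter(x, y, threshold):
        return SpecificityCall("", x, y, r, "unclassified", False)
    if abs(y) <= epsilon < abs(x):
        label = "IUGR_dominant"
    elif abs(x) <= epsilon < abs(y):
        label = "PE_dominant"
    elif abs(y - x) <= epsilon:
        label = "equal"
    elif abs(y + x) <= epsilon:
        label = "equal_reversed"
    else:
        label = "mixed"
    return SpecificityCall("", x, y, r, label, True)


def classify_table(
    pairs: pd.DataFrame,
    epsilon: float = EPSILON,
    threshold: float = FC_THRESHOLD,
) -> pd.DataFrame:
    """Classify every gene of an (x, y) pair table (index = gene)."""
    rows = []
    for gene, row in pairs.iterrows():
        call = classify(float(row["x"]), float(row["y"]),
                        epsilon=epsilon, threshold=threshold)
        rows.append({"gene": gene, "x": call.x, "y": call.y, "r": call.r,
                     "class": call.label, "retained": call.retained})
    return pd.DataFrame(rows).set_index("gene")


def rank_dominant(
    calls: pd.DataFrame, disease: str, n: int = 3
) -> list[str]:
    """Top-n genes dominated by one disease, by effect severity.

    For IUGR: IUGR_dominant genes ordered by decreasing ``|x|``, then (if
    fewer than n) mixed genes with ``|x| > |y|`` by decreasing ``|x|``;
    symmetric on ``|y|`` for PE.  Ties break on gene id.  When fewer than
    n genes qualify, all of them are returned.
    """
    if disease not in ("IUGR", "PE"):
        raise ValueError("disease must be 'IUGR' or 'PE'")
    col, other = ("x", "y") if disease == "IUGR" else ("y", "x")
    label = f"{disease}_dominant"

    def ordered(subset: pd.DataFrame) -> list[str]:
        mag = subset[col].abs()
        order = sorted(subset.index, key=lambda g: (-mag[g], g))
        return order

    primary = ordered(calls[calls["class"] == label])
    fallback = ordered(calls[(calls["class"] == "mixed")
                             & (calls[col].abs() > calls[other].abs())])
    return (primary + fallback)[:n]


def intersect_targets(
    significant: Iterable[str],
    calls: pd.DataFrame,
    stats_table: pd.DataFrame | None = None,
    n: int = 3,
) -> pd.DataFrame:
    """Final targets: significant genes that are top-n dominant or equal-class.

    Each target row carries the specificity class, coordinates, the rank
    variable and, when ``stats_table`` is given (indexed by gene with at
    least ``h`` and ``p``), the group-test annotation.
    """
    significant = set(significant)
    top_iugr = rank_dominant(calls, "IUGR", n=n)
    top_pe = rank_dominant(calls, "PE", n=n)
    rows = []
    for gene in calls.index:
        cls = calls.at[gene, "class"]
        in_top = gene in top_iugr or gene in top_pe
        if gene not in significant:
            continue
        if not (in_top or cls in ("equal", "equal_reversed")):
            continue
        row = {
            "gene": gene,
            "class": cls,
            "x": calls.at[gene, "x"],
            "y": calls.at[gene, "y"],
            "r": calls.at[gene, "r"],
            "top3_iugr": gene in top_iugr,
            "top3_pe": gene in top_pe,
        }
        if stats_table is not None and gene in stats_table.index:
            row["kw_h"] = stats_table.at[gene, "h"]
            row["kw_p"] = stats_table.at[gene, "p"]
        rows.append(row)
    columns = ["gene", "class", "x", "y", "r", "top3_iugr", "top3_pe"]
    if stats_table is not None:
        columns += ["kw_h", "kw_p"]
    if not rows:
        return pd.DataFrame(columns=columns).set_index("gene")
    return pd.DataFrame(rows).set_index("gene")
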