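"""RNA-QC filtering and comparative-Ct (2^-ddCt) relative quantification.

The comparative threshold-cycle method expresses each target gene's
abundance relative to stable reference genes and to a control group:

    dCt(sample, target)  = Ct(target) - mean_ref Ct(reference)
    ddCt(sample, target) = dCt(sample, target) - mean over control samples
    fold change          = 2 ** -ddCt,   log2 FC = -ddCt

Normalization against the reference-gene mean removes sample-level
offsets (loading, RNA input) exactly: adding a constant to every Ct of a
sample leaves dCt unchanged.  Technical replicates, when present, are
averaged per biological sample before dCt.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .tabular_io import TableFormatError

__all__ = [
    "QC_THRESHOLDS",
    "qc_filter",
    "average_replicates",
    "compute_delta_ct",
    "compute_fold_change",
    "group_log_fc",
]

#: Strict RNA quality thresholds: a sample passes only if it exceeds all four.
QC_THRESHOLDS = {"rin": 6.0, "a260_280": 2.0, "a260_230": 1.8, "yield_ng_ul": 5.0}

META_COLS = ("sample_id", "group", "replicate")


def qc_filter(qc: pd.DataFrame) -> list[str]:
    """Sample ids passing all four strict RNA-quality thresholds.

    RIN > 6, A260/280 > 2.0, A260/230 > 1.8 and yield > 5 ng/ul; equality
    at any boundary fails.
    """
    if qc["sample_id"].duplicated().any():
        dup = qc["sample_id"][qc["sample_id"].duplicated()].iloc[0]
        raise TableFormatError(f"duplicate QC record for sample {dup!r}")
    passing = np.ones(len(qc), dtype=bool)
    for col, threshold in QC_THRESHOLDS.items():
        passing &= qc[col].to_numpy(dtype=float) > threshold
    return qc.loc[passing, "sample_id"].tolist()


def _gene_columns(ct: pd.DataFrame) -> list[str]:
    return [c for c in ct.columns if c not in META_COLS]


def average_replicates(ct: pd.DataFrame) -> pd.DataFrame:
    """Average technical replicates to one Ct row per biological sample."""
    genes = _gene_columns(ct)
    grouped = ct.groupby("sample_id", sort=False)
    out = pd.concat([grouped["group"].first(), grouped[genes].mean()], axis=1)
    return out.reset_index()


def compute_delta_ct(
    ct: pd.DataFrame,
    reference_genes: Sequence[str] = ("UBQ", "YWHAZ"),
    samples: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-sample dCt for every target gene.

    ``dCt = Ct(target) - mean(Ct of the reference genes)`` within each
    sample.  ``samples`` optionally restricts to QC-passing ids.  Every
    reference gene must be measured in every retained sample.
    """
    reference_genes = list(reference_genes)
    if not reference_genes:
        raise ValueError("at least one reference gene is required")
    table = average_replicates(ct)
    if samples is not None:
        keep = set(samples)
        table = table[table["sample_id"].isin(keep)].reset_index(drop=True)
        if table.empty:
            raise ValueError("no samples left after QC restriction")
    genes = _gene_columns(table)
    missing = [g for g in reference_genes if g not in genes]
    if missing:
        raise TableFormatError(f"reference genes not measured: {missing}")
    ref_values = table[reference_genes].to_numpy(dtype=float)
    if np.isnan(ref_values).any():
        raise TableFormatError("missing reference Ct in at least one sample")
    ref_mean = ref_values.mean(axis=1)
    targets = [g for g in genes if g not in reference_genes]
    delta = table[targets].to_numpy(dtype=float) - ref_mean[:, None]
    out = pd.DataFrame(delta, columns=targets)
    out.insert(0, "sample_id", table["sample_id"].to_numpy())
    out.insert(1, "group", table["group"].to_numpy())
    return out


def compute_fold_change(
    delta: pd.DataFrame, control_group: str = "term"
) -> pd.DataFrame:
    """Long-format fold-change table from a dCt table.

    ``ddCt`` references the arithmetic mean dCt of the control group per
    gene; ``fc = 2 ** -ddCt`` and ``log2_fc = -ddCt``, so the control
    group's mean log2 FC is exactly 0 for every gene.
    """
    controls = delta["group"] == control_group
    if not controls.any():
        raise ValueError(f"control group {control_group!r} is empty")
    targets = [c for c in delta.columns if c not in ("sample_id", "group")]
    control_mean = delta.loc[controls, targets].mean(axis=0)
    rows = []
    for gene in targets:
        ddct = delta[gene].to_numpy(dtype=float) - control_mean[gene]
        rows.append(pd.DataFrame({
            "sample_id": delta["sample_id"],
            "group": delta["group"],
            "gene": gene,
            "delta_ct": delta[gene],
            "ddct": ddct,
            "fc": np.exp2(-ddct),
            "log2_fc": -ddct,
        }))
    return pd.concat(rows, ignore_index=True)


@dataclass(frozen=True)
class FoldChangePair:
    """Per-gene average log2 FC in isolated IUGR (x) and isolated PE (y)."""

    gene: str
    x: float
    y: float


def group_log_fc(
    fc: pd.DataFrame,
    iugr_group: str = "IUGR",
    pe_group: str = "PE",
) -> pd.DataFrame:
    """Per-gene (x, y) = mean log2 FC over the IUGR and PE groups.

    Only the isolated disease groups enter: combined PE+IUGR samples are
    excluded from both coordinates (they remain in the group testing as a
    fifth group).
    """
    for group, axis in ((iugr_group, "x"), (pe_group, "y")):
        if not (fc["group"] == group).any():
            raise ValueError(f"group {group!r} absent; cannot compute {axis}")
    x = (fc[fc["group"] == iugr_group]
         .groupby("gene", sort=True)["log2_fc"].mean())
    y = (fc[fc["group"] == pe_group]
         .groupby("gene", sort=True)["log2_fc"].mean())
    out = pd.DataFrame({"x": x, "y": y})
    out.index.name = "gene"
    return out
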