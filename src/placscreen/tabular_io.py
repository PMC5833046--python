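"""Readers and writers for the tab-separated formats the pipeline touches.

Every reader validates and raises :class:`TableFormatError` on malformed
input instead of silently coercing; every writer is deterministic (stable
column order, fixed ``%.6g`` float formatting) so repeated runs are
byte-identical.  Gene and sample identifiers are case-sensitive throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

__all__ = [
    "TableFormatError",
    "StudyMeta",
    "ExpressionStudy",
    "SampleAccounting",
    "read_study_metadata",
    "sample_accounting",
    "read_expression_matrix",
    "read_sample_annotations",
    "read_ct_table",
    "read_qc_table",
    "read_edge_list",
    "write_edge_list",
    "read_table",
    "write_results_table",
    "write_matrix",
    "write_newick",
    "newick_string",
]

FLOAT_FORMAT = "%.6g"


class TableFormatError(ValueError):
    """Raised when an on-disk table violates the documented dialect."""


# ---------------------------------------------------------------------------
# Study metadata (the published multi-study design table)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StudyMeta:
    """One microarray study: identifiers, platform and arm sizes.

    A missing disease arm is recorded as a count of 0.
    """

    study_id: str
    accession: str = ""
    platform: str = ""
    tissue: str = ""
    n_control: int = 0
    n_iugr: int = 0
    n_pe: int = 0

    def __post_init__(self) -> None:
        for name in ("n_control", "n_iugr", "n_pe"):
            if getattr(self, name) < 0:
                raise TableFormatError(
                    f"study {self.study_id!r}: {name} must be >= 0"
                )


@dataclass(frozen=True)
class SampleAccounting:
    n_total: int
    n_control: int
    n_iugr: int
    n_pe: int


_META_COUNT_COLS = ("n_control", "n_iugr", "n_pe")


def read_study_metadata(path: str | Path) -> list[StudyMeta]:
    """Read the tab-separated study-metadata table.

    Required columns: ``study_id``, ``n_control``, ``n_iugr``, ``n_pe``;
    optional: ``accession``, ``platform``, ``tissue``.  Blank counts denote
    a missing arm and become 0.  Duplicate study ids and negative or
    non-integer counts are rejected.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.empty:
        raise TableFormatError(f"{path}: no study rows")
    missing = {"study_id", *_META_COUNT_COLS} - set(df.columns)
    if missing:
        raise TableFormatError(f"{path}: missing columns {sorted(missing)}")
    if df["study_id"].duplicated().any():
        dup = df["study_id"][df["study_id"].duplicated()].iloc[0]
        raise TableFormatError(f"{path}: duplicate study id {dup!r}")
    metas = []
    for _, row in df.iterrows():
        counts = {}
        for col in _META_COUNT_COLS:
            raw = row[col].strip()
            if raw == "":
                counts[col] = 0
                continue
            try:
                value = int(raw)
            except ValueError as exc:
                raise TableFormatError(
                    f"{path}: study {row['study_id']!r}: "
                    f"malformed count {col}={raw!r}"
                ) from exc
            counts[col] = value
        metas.append(
            StudyMeta(
                study_id=row["study_id"],
                accession=row.get("accession", ""),
                platform=row.get("platform", ""),
                tissue=row.get("tissue", ""),
                **counts,
            )
        )
    return metas


def sample_accounting(metas: Sequence[StudyMeta]) -> SampleAccounting:
    """Column sums over the study table; total = control + IUGR + PE."""
    if not metas:
        raise TableFormatError("sample_accounting requires at least one study")
    n_control = sum(m.n_control for m in metas)
    n_iugr = sum(m.n_iugr for m in metas)
    n_pe = sum(m.n_pe for m in metas)
    return SampleAccounting(
        n_total=n_control + n_iugr + n_pe,
        n_control=n_control,
        n_iugr=n_iugr,
        n_pe=n_pe,
    )


# ---------------------------------------------------------------------------
# Expression studies
# ---------------------------------------------------------------------------

@dataclass
class ExpressionStudy:
    """One study's log2 expression matrix (genes x samples) plus group labels."""

    study_id: str
    matrix: pd.DataFrame
    groups: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        idx = self.matrix.index
        if idx.duplicated().any():
            raise TableFormatError(
                f"study {self.study_id!r}: duplicate gene ids"
            )
        if self.matrix.columns.duplicated().any():
            raise TableFormatError(
                f"study {self.study_id!r}: duplicate sample ids"
            )
        unlabeled = [s for s in self.matrix.columns if s not in self.groups]
        if unlabeled:
            raise TableFormatError(
                f"study {self.study_id!r}: samples without group label: "
                f"{unlabeled[:5]}"
            )

    @property
    def genes(self) -> list[str]:
        return list(self.matrix.index)

    @property
    def samples(self) -> list[str]:
        return list(self.matrix.columns)

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.matrix.columns if self.groups[s] == group]


def read_sample_annotations(path: str | Path) -> pd.DataFrame:
    """Read the sample annotation table: sample_id, group[, study_id]."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = {"sample_id", "group"} - set(df.columns)
    if missing:
        raise TableFormatError(f"{path}: missing columns {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        raise TableFormatError(f"{path}: duplicate sample id")
    return df


def _read_numeric_matrix(path: str | Path, index_name: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        raise TableFormatError(f"{path}: duplicate {index_name} ids")
    if df.columns.duplicated().any():
        raise TableFormatError(f"{path}: duplicate column ids")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise TableFormatError(f"{path}: non-numeric cell: {exc}") from exc
    if df.isna().any().any():
        raise TableFormatError(f"{path}: missing values are not allowed")
    return df


def read_expression_matrix(
    path: str | Path,
    annotations: pd.DataFrame | Mapping[str, str],
    study_id: str | None = None,
) -> ExpressionStudy:
    """Read a genes-x-samples log2 matrix and attach group labels.

    ``annotations`` is either the annotation table from
    :func:`read_sample_annotations` or a plain ``sample -> group`` mapping.
    """
    matrix = _read_numeric_matrix(path, "gene")
    if isinstance(annotations, pd.DataFrame):
        groups = dict(zip(annotations["sample_id"], annotations["group"]))
    else:
        groups = dict(annotations)
    sid = study_id if study_id is not None else Path(path).stem
    return ExpressionStudy(study_id=sid, matrix=matrix, groups=groups)


# ---------------------------------------------------------------------------
# Ct / QC tables
# ---------------------------------------------------------------------------

def read_ct_table(path: str | Path) -> pd.DataFrame:
    """Read a qPCR Ct table.

    Dialect: columns ``sample_id``, ``group``, optional ``replicate``, then
    one numeric Ct column per gene.  Rows sharing a ``sample_id`` are
    technical replicates of the same biological sample.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = {"sample_id", "group"} - set(df.columns)
    if missing:
        raise TableFormatError(f"{path}: missing columns {sorted(missing)}")
    meta_cols = [c for c in ("sample_id", "group", "replicate") if c in df.columns]
    gene_cols = [c for c in df.columns if c not in meta_cols]
    if not gene_cols:
        raise TableFormatError(f"{path}: no gene Ct columns")
    if "replicate" not in df.columns and df["sample_id"].duplicated().any():
        raise TableFormatError(
            f"{path}: duplicate sample id without a replicate column"
        )
    try:
        df[gene_cols] = df[gene_cols].astype(float)
    except ValueError as exc:
        raise TableFormatError(f"{path}: non-numeric Ct value: {exc}") from exc
    grp = df.groupby("sample_id")["group"].nunique()
    if (grp > 1).any():
        bad = grp[grp > 1].index[0]
        raise TableFormatError(f"{path}: sample {bad!r} has conflicting groups")
    return df


def read_qc_table(path: str | Path) -> pd.DataFrame:
    """Read the per-sample RNA QC table.

    Columns: ``sample_id``, ``rin``, ``a260_280``, ``a260_230``,
    ``yield_ng_ul`` (all numeric, >= 0).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"sample_id", "rin", "a260_280", "a260_230", "yield_ng_ul"}
    missing = required - set(df.columns)
    if missing:
        raise TableFormatError(f"{path}: missing columns {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        raise TableFormatError(f"{path}: duplicate sample id in QC table")
    num_cols = ["rin", "a260_280", "a260_230", "yield_ng_ul"]
    try:
        df[num_cols] = df[num_cols].astype(float)
    except ValueError as exc:
        raise TableFormatError(f"{path}: non-numeric QC value: {exc}") from exc
    if (df[num_cols] < 0).any().any():
        raise TableFormatError(f"{path}: negative QC value")
    return df


# ---------------------------------------------------------------------------
# Interaction edge lists
# ---------------------------------------------------------------------------

def read_edge_list(path: str | Path) -> pd.DataFrame:
    """Read a three-column headerless edge list: nodeA <TAB> nodeB <TAB> score."""
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, names=["node_a", "node_b", "score"],
            dtype={"node_a": str, "node_b": str},
        )
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=["node_a", "node_b", "score"])
    try:
        df["score"] = df["score"].astype(float)
    except ValueError as exc:
        raise TableFormatError(f"{path}: non-numeric score: {exc}") from exc
    if df["score"].isna().any() or df[["node_a", "node_b"]].isna().any().any():
        raise TableFormatError(f"{path}: malformed edge row")
    if ((df["score"] < 0) | (df["score"] > 1)).any():
        raise TableFormatError(f"{path}: confidence score outside [0, 1]")
    return df


def write_edge_list(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False,
              float_format=FLOAT_FORMAT)


# ---------------------------------------------------------------------------
# Generic results / matrix output
# ---------------------------------------------------------------------------

def read_table(path: str | Path, index_col: int | None = None) -> pd.DataFrame:
    """Read back a results table written by :func:`write_results_table`."""
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_results_table(
    df: pd.DataFrame, path: str | Path, index: bool = False
) -> None:
    """Write a results table deterministically (tab-separated, %.6g floats)."""
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT)


def write_matrix(df: pd.DataFrame, path: str | Path,
                 float_format: str = "%.10g") -> None:
    """Write a numeric matrix with its index column.

    Matrices use 10 significant digits so a write/read round trip preserves
    values far below any tolerance used downstream.
    """
    df.to_csv(path, sep="\t", index=True, float_format=float_format)


# ---------------------------------------------------------------------------
# Newick export for dendrograms
# ---------------------------------------------------------------------------

def newick_string(dendrogram) -> str:
    """Render a dendrogram as a newick string.

    ``dendrogram`` duck-types the clustering output: attributes ``labels``
    (leaf names, ordered by leaf index) and ``merges`` (sequence of
    ``(a, b, height, new_id)`` with leaves numbered ``0..n-1`` and internal
    nodes ``n..2n-2``).  Node height equals its merge height (leaves sit at
    height 0) and each branch length is parent height minus child height,
    so the tree is ultrametric with root height equal to the final merge
    height.
    """
    labels = list(dendrogram.labels)
    n = len(labels)
    if n == 1:
        return f"{labels[0]}:0;"
    height = {i: 0.0 for i in range(n)}
    children: dict[int, tuple[int, int]] = {}
    smallest = {i: labels[i] for i in range(n)}
    for a, b, h, new_id in dendrogram.merges:
        height[new_id] = h
        children[new_id] = (a, b)
        smallest[new_id] = min(smallest[a], smallest[b])
    root = dendrogram.merges[-1][3]

    def ordered_children(node: int) -> tuple[int, int]:
        a, b = children[node]
        return (a, b) if smallest[a] <= smallest[b] else (b, a)

    def render(node: int, parent_h: float) -> str:
        length = parent_h - height[node]
        if node < n:
            return f"{labels[node]}:{FLOAT_FORMAT % length}"
        inner = ",".join(render(c, height[node])
                         for c in ordered_children(node))
        return f"({inner}):{FLOAT_FORMAT % length}"

    inner = ",".join(render(c, height[root]) for c in ordered_children(root))
    return f"({inner});"


def write_newick(dendrogram, path: str | Path) -> None:
    Path(path).write_text(newick_string(dendrogram) + "\n")
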