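"""Stage orchestration shared by the command-line interface.

Each stage reads and writes only its declared files under one output
directory, so running the stages individually in order is identical to
running ``all``.  Every output is tab-separated text (plus newick for the
dendrograms) written with fixed float formatting, and the only source of
randomness is the master seed, so a repeated run is byte-identical.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, fields
from pathlib import Path

import pandas as pd

from . import (cluster_viz, graph_cluster, group_stats, meta_screen,
               qpcr_quant, specificity, synthetic_data, tabular_io)

__all__ = ["PipelineConfig", "read_pipeline_config", "STAGES", "run_stage"]

log = logging.getLogger("placscreen")


@dataclass
class PipelineConfig:
    """All pipeline thresholds and study conditions in one place."""

    seed: int = 0
    n_genes: int = 200
    noise_sd: float = 0.3
    min_studies: int = 4
    top_k: int = 12
    fc_threshold: float = 1.14
    epsilon: float = 0.2
    alpha: float = 0.05
    edge_min_score: float = 0.4
    inflation: float = 2.0
    n_top_dominant: int = 3
    control_group_study: str = "control"
    control_group_ct: str = "term"

    def __post_init__(self) -> None:
        for name in ("n_genes", "min_studies", "top_k", "n_top_dominant"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("fc_threshold", "epsilon", "alpha", "edge_min_score"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.inflation <= 1.0:
            raise ValueError("inflation must exceed 1")


_FIELD_TYPES = {f.name: f.type for f in fields(PipelineConfig)}


def read_pipeline_config(path: str | Path) -> PipelineConfig:
    """Parse a flat ``key = value`` config file; unknown keys are errors."""
    values: dict[str, object] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value'")
        key, _, value = (part.strip() for part in line.partition("="))
        if key not in _FIELD_TYPES:
            raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
        kind = _FIELD_TYPES[key]
        if kind in ("int", int):
            values[key] = int(value)
        elif kind in ("float", float):
            values[key] = float(value)
        else:
            values[key] = value
    return PipelineConfig(**values)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:12]


def _log_inputs(stage: str, seed: int, paths: list[Path]) -> None:
    for p in paths:
        log.info("stage=%s seed=%d input=%s sha256=%s", stage, seed, p.name,
                 _digest(p))


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def run_simulate(cfg: PipelineConfig, out_dir: Path) -> None:
    sim = synthetic_data.default_cohort_config(
        n_genes=cfg.n_genes, seed=cfg.seed, noise_sd=cfg.noise_sd)
    paths = synthetic_data.write_fixture_bundle(sim, out_dir / "fixtures")
    log.info("stage=simulate seed=%d wrote %d fixture files", cfg.seed, len(paths))


def run_screen(cfg: PipelineConfig, out_dir: Path) -> None:
    fixtures = out_dir / "fixtures"
    ann = tabular_io.read_sample_annotations(fixtures / "sample_annotations.tsv")
    flags_df = pd.read_csv(fixtures / "gene_annotations.tsv", sep="\t")
    flags = {row["gene"]: str(row["placenta_annotated"]).lower() == "true"
             for _, row in flags_df.iterrows()}
    study_paths = sorted(fixtures.glob("study_*.tsv"))
    _log_inputs("screen", cfg.seed, study_paths)
    stage_dir = out_dir / "screen"
    stage_dir.mkdir(parents=True, exist_ok=True)
    results = []
    for path in study_paths:
        study_id = path.stem.removeprefix("study_")
        sub = ann[ann["study_id"] == study_id]
        study = tabular_io.read_expression_matrix(path, sub, study_id=study_id)
        study.matrix = meta_screen.quantile_normalize(study.matrix)
        present = set(study.groups.values())
        for contrast in ("IUGR", "PE"):
            if contrast not in present:
                continue
            de = meta_screen.de_statistics(
                study, contrast, control_group=cfg.control_group_study)
            tabular_io.write_results_table(
                de.table.reset_index(),
                stage_dir / f"de_{study_id}_{contrast}.tsv")
            results.append(de)
    candidates = meta_screen.select_candidates(
        results, flags, min_studies=cfg.min_studies, k=cfg.top_k)
    tabular_io.write_results_table(
        candidates.table.reset_index(), stage_dir / "candidates.tsv")
    log.info("stage=screen selected %d candidates", len(candidates.selected))


def run_qpcr(cfg: PipelineConfig, out_dir: Path) -> None:
    fixtures = out_dir / "fixtures"
    ct_path, qc_path = fixtures / "ct_table.tsv", fixtures / "qc_table.tsv"
    _log_inputs("qpcr", cfg.seed, [ct_path, qc_path])
    ct = tabular_io.read_ct_table(ct_path)
    qc = tabular_io.read_qc_table(qc_path)
    sim = synthetic_data.read_config(fixtures / "simulation_config.txt")
    passing = qpcr_quant.qc_filter(qc)
    delta = qpcr_quant.compute_delta_ct(
        ct, reference_genes=sim.reference_genes, samples=passing)
    fc = qpcr_quant.compute_fold_change(
        delta, control_group=cfg.control_group_ct)
    pairs = qpcr_quant.group_log_fc(fc)
    stage_dir = out_dir / "qpcr"
    stage_dir.mkdir(parents=True, exist_ok=True)
    tabular_io.write_results_table(fc, stage_dir / "fold_changes.tsv")
    tabular_io.write_results_table(pairs.reset_index(), stage_dir / "pairs.tsv")
    matrix = fc.pivot(index="gene", columns="sample_id", values="log2_fc")
    sample_order = list(dict.fromkeys(fc["sample_id"]))
    tabular_io.write_matrix(matrix[sample_order], stage_dir / "log2fc_matrix.tsv")
    groups = fc.drop_duplicates("sample_id")[["sample_id", "group"]]
    tabular_io.write_results_table(groups, stage_dir / "sample_groups.tsv")
    log.info("stage=qpcr %d samples passed QC, %d genes quantified",
             len(passing), matrix.shape[0])


def run_stats(cfg: PipelineConfig, out_dir: Path) -> None:
    fc_path = out_dir / "qpcr" / "fold_changes.tsv"
    _log_inputs("stats", cfg.seed, [fc_path])
    fc = tabular_io.read_table(fc_path)
    table = group_stats.group_test_table(
        fc, control=cfg.control_group_ct, alpha=cfg.alpha)
    stage_dir = out_dir / "stats"
    stage_dir.mkdir(parents=True, exist_ok=True)
    tabular_io.write_results_table(table.reset_index(),
                                   stage_dir / "group_tests.tsv")
    significant = sorted(group_stats.flag_significant(table, alpha=cfg.alpha))
    (stage_dir / "significant.txt").write_text(
        "".join(f"{g}\n" for g in significant))
    log.info("stage=stats %d/%d genes significant at alpha=%g",
             len(significant), len(table), cfg.alpha)


def run_cluster(cfg: PipelineConfig, out_dir: Path) -> None:
    matrix_path = out_dir / "qpcr" / "log2fc_matrix.tsv"
    groups_path = out_dir / "qpcr" / "sample_groups.tsv"
    _log_inputs("cluster", cfg.seed, [matrix_path, groups_path])
    matrix = pd.read_csv(matrix_path, sep="\t", index_col=0)
    groups = pd.read_csv(groups_path, sep="\t", index_col=0)["group"]
    gene_tree = cluster_viz.average_linkage(
        cluster_viz.centered_correlation_distance(matrix, axis="rows"),
        axis="genes")
    sample_tree = cluster_viz.average_linkage(
        cluster_viz.centered_correlation_distance(matrix, axis="columns"),
        axis="samples")
    export = cluster_viz.build_heatmap(matrix, gene_tree, sample_tree,
                                       annotations=groups)
    stage_dir = out_dir / "cluster"
    stage_dir.mkdir(parents=True, exist_ok=True)
    tabular_io.write_matrix(export.matrix, stage_dir / "heatmap_matrix.tsv")
    (stage_dir / "row_order.txt").write_text(
        "".join(f"{g}\n" for g in export.row_order))
    (stage_dir / "col_order.txt").write_text(
        "".join(f"{s}\n" for s in export.col_order))
    tabular_io.write_results_table(
        export.annotations.rename("group").rename_axis("sample_id").reset_index(),
        stage_dir / "annotations.tsv")
    tabular_io.write_newick(gene_tree, stage_dir / "gene_tree.nwk")
    tabular_io.write_newick(sample_tree, stage_dir / "sample_tree.nwk")
    log.info("stage=cluster clustered %d genes x %d samples",
             len(export.row_order), len(export.col_order))


def run_specificity(cfg: PipelineConfig, out_dir: Path) -> None:
    pairs_path = out_dir / "qpcr" / "pairs.tsv"
    _log_inputs("specificity", cfg.seed, [pairs_path])
    pairs = tabular_io.read_table(pairs_path, index_col=0)
    calls = specificity.classify_table(
        pairs, epsilon=cfg.epsilon, threshold=cfg.fc_threshold)
    stage_dir = out_dir / "specificity"
    stage_dir.mkdir(parents=True, exist_ok=True)
    tabular_io.write_results_table(calls.reset_index(),
                                   stage_dir / "scatter.tsv")
    log.info("stage=specificity %d/%d genes retained by the FC filter",
             int(calls["retained"].sum()), len(calls))


def run_mcl(cfg: PipelineConfig, out_dir: Path) -> None:
    edges_path = out_dir / "fixtures" / "interactions.tsv"
    _log_inputs("mcl", cfg.seed, [edges_path])
    edges = tabular_io.read_edge_list(edges_path)
    graph = graph_cluster.filter_edges(
        graph_cluster.graph_from_edges(edges), min_score=cfg.edge_min_score)
    result = graph_cluster.mcl(graph, inflation=cfg.inflation)
    stage_dir = out_dir / "mcl"
    stage_dir.mkdir(parents=True, exist_ok=True)
    (stage_dir / "clusters.tsv").write_text(
        "".join("\t".join(c) + "\n" for c in result.clusters))
    tabular_io.write_results_table(
        graph_cluster.clusters_to_table(result), stage_dir / "membership.tsv")
    log.info("stage=mcl %d clusters (converged=%s after %d iterations)",
             len(result.clusters), result.converged, result.n_iterations)


def run_report(cfg: PipelineConfig, out_dir: Path) -> None:
    stats_path = out_dir / "stats" / "group_tests.tsv"
    scatter_path = out_dir / "specificity" / "scatter.tsv"
    _log_inputs("report", cfg.seed, [stats_path, scatter_path])
    stats_table = tabular_io.read_table(stats_path, index_col=0)
    calls = tabular_io.read_table(scatter_path, index_col=0)
    significant = group_stats.flag_significant(stats_table, alpha=cfg.alpha)
    targets = specificity.intersect_targets(
        significant, calls, stats_table=stats_table, n=cfg.n_top_dominant)
    stage_dir = out_dir / "report"
    stage_dir.mkdir(parents=True, exist_ok=True)
    tabular_io.write_results_table(targets.reset_index(),
                                   stage_dir / "final_targets.tsv")
    log.info("stage=report %d final targets", len(targets))


STAGES = {
    "simulate": run_simulate,
    "screen": run_screen,
    "qpcr": run_qpcr,
    "stats": run_stats,
    "cluster": run_cluster,
    "specificity": run_specificity,
    "mcl": run_mcl,
    "report": run_report,
}

#: execution order for the chained run
STAGE_ORDER = ["simulate", "screen", "qpcr", "stats", "cluster",
               "specificity", "mcl", "report"]


def run_stage(name: str, cfg: PipelineConfig, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if name == "all":
        for stage in STAGE_ORDER:
            STAGES[stage](cfg, out)
        return
    if name not in STAGES:
        raise ValueError(f"unknown stage {name!r}")
    STAGES[name](cfg, out)
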