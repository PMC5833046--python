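"""Synthetic multi-study cohorts with planted disease effects.

This module generates everything the downstream stages consume, with known
ground truth, so the whole pipeline is testable without any download:

* multi-study log2 expression matrices whose disease arms carry planted
  per-gene log2 effects (additive Gaussian noise on the log2 scale);
* a qPCR Ct table for a five-group clinical cohort (term, preterm, IUGR,
  PE, PE+IUGR) with two stable reference genes, per-sample loading offsets
  and technical triplicates (Gaussian cycle noise per replicate);
* per-sample RNA QC records with a configurable failure fraction;
* a confidence-weighted interaction edge list with planted substrate-class
  communities.

Every gene belongs to one effect class: ``null`` (no disease effect),
``iugr_only``, ``pe_only``, ``equal`` (same signed effect in both
diseases) or ``equal_reversed`` (equal magnitude, opposite sign).  The
combined PE+IUGR group receives the sum of both disease effects.  All
randomness flows from one master seed through deterministically spawned
child streams, so an identical configuration yields byte-identical files.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .tabular_io import ExpressionStudy, write_matrix, write_results_table

__all__ = [
    "EFFECT_CLASSES",
    "DEFAULT_GROUP_SIZES",
    "DEFAULT_STUDY_DESIGNS",
    "StudyDesign",
    "SimulationConfig",
    "PlantedTruth",
    "simulate_studies",
    "simulate_ct_table",
    "simulate_qc_table",
    "simulate_interaction_graph",
    "default_cohort_config",
    "write_fixture_bundle",
    "write_config",
    "read_config",
]

EFFECT_CLASSES = ("null", "iugr_only", "pe_only", "equal", "equal_reversed")

#: Five-group clinical cohort sizes (term/preterm controls and disease arms).
DEFAULT_GROUP_SIZES: dict[str, int] = {
    "term": 13, "preterm": 7, "IUGR": 8, "PE": 5, "PE+IUGR": 10,
}

DISEASE_GROUPS = ("IUGR", "PE", "PE+IUGR")


@dataclass(frozen=True)
class StudyDesign:
    """Arm sizes of one expression study; a 0 count means the arm is absent."""

    study_id: str
    n_control: int
    n_iugr: int
    n_pe: int


#: Seven mixed designs (some studies lack an IUGR or a PE arm), mirroring a
#: typical multi-study compendium: 129 controls, 67 IUGR, 62 PE in total.
DEFAULT_STUDY_DESIGNS: tuple[StudyDesign, ...] = (
    StudyDesign("S1", 3, 6, 0),
    StudyDesign("S2", 8, 8, 8),
    StudyDesign("S3", 8, 8, 0),
    StudyDesign("S4", 37, 0, 23),
    StudyDesign("S5", 11, 0, 12),
    StudyDesign("S6", 40, 27, 19),
    StudyDesign("S7", 22, 18, 0),
)


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults are the study conditions.

    ``effect_size`` is the base planted magnitude in log2 units; a per-gene
    ``effect_magnitude`` entry overrides it and ``effect_sign`` flips the
    direction (+1 up-regulated in disease, -1 down).  ``noise_sd`` is the
    per-measurement Gaussian SD, applied on the log2 scale for expression
    values and on the cycle scale for each individual Ct replicate.
    """

    genes: list[str]
    effect_class: dict[str, str] = field(default_factory=dict)
    effect_size: float = 1.0
    effect_magnitude: dict[str, float] = field(default_factory=dict)
    effect_sign: dict[str, int] = field(default_factory=dict)
    noise_sd: float = 0.3
    group_sizes: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    study_designs: tuple[StudyDesign, ...] = DEFAULT_STUDY_DESIGNS
    reference_genes: tuple[str, ...] = ("UBQ", "YWHAZ")
    ct_baseline: float = 25.0
    n_replicates: int = 3
    sample_offset_sd: float = 0.5
    qc_fail_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("gene list must not be empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene ids")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if not 0 <= self.qc_fail_fraction <= 1:
            raise ValueError("qc_fail_fraction must lie in [0, 1]")
        for group, n in self.group_sizes.items():
            if n < 2:
                raise ValueError(f"group {group!r} needs >= 2 samples")
        for gene, cls in self.effect_class.items():
            if cls not in EFFECT_CLASSES:
                raise ValueError(f"unknown effect class {cls!r} for {gene!r}")
            if gene not in self.genes:
                raise ValueError(f"effect class for unknown gene {gene!r}")
        overlap = set(self.reference_genes) & set(self.genes)
        if overlap:
            raise ValueError(f"reference genes duplicated in gene list: {overlap}")

    # -- planted effects ----------------------------------------------------

    def gene_class(self, gene: str) -> str:
        return self.effect_class.get(gene, "null")

    def planted_effects(self, gene: str) -> tuple[float, float]:
        """Signed planted log2 effects (IUGR, PE) for one gene."""
        cls = self.gene_class(gene)
        mag = self.effect_magnitude.get(gene, self.effect_size)
        mag *= self.effect_sign.get(gene, 1)
        if cls == "null":
            return 0.0, 0.0
        if cls == "iugr_only":
            return mag, 0.0
        if cls == "pe_only":
            return 0.0, mag
        if cls == "equal":
            return mag, mag
        return mag, -mag  # equal_reversed

    def truth(self) -> "PlantedTruth":
        rows = []
        for gene in self.genes:
            e_i, e_p = self.planted_effects(gene)
            cls = self.gene_class(gene)
            rows.append((gene, cls, e_i, e_p, cls != "null"))
        table = pd.DataFrame(
            rows,
            columns=["gene", "effect_class", "effect_iugr", "effect_pe",
                     "significant"],
        ).set_index("gene")
        return PlantedTruth(table=table)


@dataclass
class PlantedTruth:
    """Ground truth per gene: class, signed log2 effects, significance flag."""

    table: pd.DataFrame

    @property
    def non_null_genes(self) -> list[str]:
        return list(self.table.index[self.table["effect_class"] != "null"])

    def expected_class(self, epsilon: float = 0.2) -> pd.Series:
        """The specificity class the planted (x, y) coordinates imply."""
        from .specificity import classify

        return pd.Series(
            {
                g: classify(row["effect_iugr"], row["effect_pe"],
                            epsilon=epsilon).label
                for g, row in self.table.iterrows()
            },
            name="expected_class",
        )


def _streams(config: SimulationConfig, purpose: str, n: int) -> list[np.random.Generator]:
    """Deterministic child generators for one purpose under the master seed."""
    # zlib.crc32 is a stable hash (str.__hash__ is salted per process)
    key = zlib.crc32(purpose.encode("utf-8"))
    root = np.random.SeedSequence(entropy=config.seed, spawn_key=(key,))
    return [np.random.Generator(np.random.PCG64(s)) for s in root.spawn(n)]


def _stream(config: SimulationConfig, purpose: str) -> np.random.Generator:
    return _streams(config, purpose, 1)[0]


# ---------------------------------------------------------------------------
# Expression studies
# ---------------------------------------------------------------------------

def simulate_studies(
    config: SimulationConfig,
) -> tuple[list[ExpressionStudy], PlantedTruth]:
    """Simulate one log2 expression matrix per study design.

    Each value is gene baseline + planted effect (in the disease arms the
    study contains) + N(0, noise_sd).  Studies with a 0 count simply omit
    that arm; a 1-sample arm is rejected.
    """
    for design in config.study_designs:
        for arm, n in (("control", design.n_control),
                       ("IUGR", design.n_iugr), ("PE", design.n_pe)):
            if n == 1:
                raise ValueError(
                    f"study {design.study_id!r}: arm {arm!r} has a single "
                    "sample; include >= 2 or omit the arm"
                )
        if design.n_control < 2:
            raise ValueError(
                f"study {design.study_id!r} needs >= 2 control samples")

    genes = config.genes
    effects = np.array([config.planted_effects(g) for g in genes])
    rngs = _streams(config, "studies", len(config.study_designs))
    studies = []
    for design, rng in zip(config.study_designs, rngs):
        baselines = rng.uniform(6.0, 12.0, size=len(genes))
        arms = [("control", design.n_control, np.zeros(len(genes))),
                ("IUGR", design.n_iugr, effects[:, 0]),
                ("PE", design.n_pe, effects[:, 1])]
        cols, labels, groups = [], [], {}
        for arm, n, effect in arms:
            for k in range(n):
                sample = f"{design.study_id}_{arm}_{k + 1}"
                noise = rng.normal(0.0, config.noise_sd, size=len(genes)) \
                    if config.noise_sd > 0 else np.zeros(len(genes))
                cols.append(baselines + effect + noise)
                labels.append(sample)
                groups[sample] = arm
        matrix = pd.DataFrame(
            np.column_stack(cols), index=pd.Index(genes, name="gene"),
            columns=labels,
        )
        studies.append(ExpressionStudy(design.study_id, matrix, groups))
    return studies, config.truth()


# ---------------------------------------------------------------------------
# qPCR cohort
# ---------------------------------------------------------------------------

def _group_effect(group: str, e_iugr: float, e_pe: float) -> float:
    if group == "IUGR":
        return e_iugr
    if group == "PE":
        return e_pe
    if group == "PE+IUGR":
        return e_iugr + e_pe  # combined phenotype = additive effects
    return 0.0


def simulate_ct_table(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, PlantedTruth]:
    """Simulate the five-group qPCR cohort.

    Returns ``(ct_table, qc_table, truth)``.  Ct of a replicate is
    ``ct_baseline(gene) - planted log2 effect(group) + sample offset +
    N(0, noise_sd)``; lower Ct means higher expression, so a positive
    planted log2 effect lowers Ct by the same number of cycles.  Reference
    genes carry the sample offset but no group effect.
    """
    if len(config.reference_genes) < 2:
        raise ValueError("at least two stable reference genes are required")
    rng = _stream(config, "ct")
    genes = list(config.genes)
    all_genes = genes + list(config.reference_genes)
    baselines = dict(zip(
        all_genes,
        config.ct_baseline + rng.uniform(-5.0, 5.0, size=len(all_genes)),
    ))
    effects = {g: config.planted_effects(g) for g in genes}

    samples = []
    for group, n in config.group_sizes.items():
        for k in range(n):
            samples.append((f"{group}_{k + 1}", group))

    offsets = (
        rng.normal(0.0, config.sample_offset_sd, size=len(samples))
        if config.sample_offset_sd > 0 else np.zeros(len(samples))
    )
    rows = []
    for (sample, group), offset in zip(samples, offsets):
        for rep in range(1, config.n_replicates + 1):
            row: dict[str, object] = {
                "sample_id": sample, "group": group, "replicate": rep,
            }
            for gene in all_genes:
                if gene in effects:
                    e = _group_effect(group, *effects[gene])
                else:
                    e = 0.0  # stable reference gene
                noise = rng.normal(0.0, config.noise_sd) \
                    if config.noise_sd > 0 else 0.0
                row[gene] = baselines[gene] - e + offset + noise
            rows.append(row)
    ct = pd.DataFrame(rows)
    qc = simulate_qc_table(config, [s for s, _ in samples])
    return ct, qc, config.truth()


def simulate_qc_table(
    config: SimulationConfig, sample_ids: Sequence[str]
) -> pd.DataFrame:
    """Per-sample RNA QC records; a configurable fraction fails the filter."""
    rng = _stream(config, "qc")
    n = len(sample_ids)
    n_fail = int(round(config.qc_fail_fraction * n))
    fail_idx = set(rng.choice(n, size=n_fail, replace=False)) if n_fail else set()
    rows = []
    for i, sample in enumerate(sample_ids):
        if i in fail_idx:
            # degraded RNA: RIN at or below the strict threshold
            rows.append((sample, rng.uniform(3.0, 6.0), rng.uniform(2.01, 2.1),
                         rng.uniform(1.85, 2.1), rng.uniform(20.0, 200.0)))
        else:
            rows.append((sample, rng.uniform(7.0, 9.8), rng.uniform(2.01, 2.15),
                         rng.uniform(1.85, 2.2), rng.uniform(20.0, 300.0)))
    return pd.DataFrame(
        rows, columns=["sample_id", "rin", "a260_280", "a260_230", "yield_ng_ul"]
    )


# ---------------------------------------------------------------------------
# Interaction graph with planted communities
# ---------------------------------------------------------------------------

def simulate_interaction_graph(
    communities: Mapping[str, Sequence[str]],
    rng: np.random.Generator | int = 0,
    intra_p: float = 0.6,
    inter_edges_per_pair: int = 2,
    intra_score: tuple[float, float] = (0.6, 0.95),
    inter_score: tuple[float, float] = (0.41, 0.5),
) -> pd.DataFrame:
    """Edge list with dense high-confidence intra-community edges.

    Every community is kept connected by a ring of edges plus random extra
    intra edges (probability ``intra_p``); a few weaker bridges join
    community pairs.  Bridge scores default to just above the 0.4
    confidence filter so community recovery is a real clustering task, not
    a connected-components one.
    """
    if isinstance(rng, int):
        rng = np.random.Generator(np.random.PCG64(rng))
    rows: list[tuple[str, str, float]] = []
    seen: set[tuple[str, str]] = set()

    def add(a: str, b: str, lo: float, hi: float) -> None:
        key = (a, b) if a < b else (b, a)
        if a == b or key in seen:
            return
        seen.add(key)
        rows.append((*key, round(float(rng.uniform(lo, hi)), 3)))

    names = sorted(communities)
    for name in names:
        members = list(communities[name])
        for i, a in enumerate(members):
            add(a, members[(i + 1) % len(members)], *intra_score)
        for i, a in enumerate(members):
            for b in members[i + 1:]:
                if rng.uniform() < intra_p:
                    add(a, b, *intra_score)
    for i, na in enumerate(names):
        for nb in names[i + 1:]:
            for _ in range(inter_edges_per_pair):
                a = communities[na][int(rng.integers(len(communities[na])))]
                b = communities[nb][int(rng.integers(len(communities[nb])))]
                add(a, b, *inter_score)
    df = pd.DataFrame(rows, columns=["node_a", "node_b", "score"])
    return df.sort_values(["node_a", "node_b"], ignore_index=True)


# ---------------------------------------------------------------------------
# Default cohort (the packaged study conditions)
# ---------------------------------------------------------------------------

def default_cohort_config(
    n_genes: int = 200, seed: int = 0, noise_sd: float = 0.3
) -> SimulationConfig:
    """The packaged synthetic cohort: 200 genes, balanced planted classes.

    8 genes per non-null class (iugr_only, pe_only, equal, equal_reversed),
    each class split 4 up / 4 down with magnitudes evenly spaced on
    [1.0, 3.0] log2 units; the remaining genes are null.  8 per class keeps
    the planted genes per disease and direction at exactly 12 (8 single-
    disease + 4 shared up + ... per direction), so in the noise-free limit
    every planted gene occupies a top-12 slot of at least one study
    contrast in the meta-screen.
    """
    per_class = 8
    if n_genes < 4 * per_class + 1:
        raise ValueError("cohort needs more genes than planted effects")
    genes = [f"G{i + 1:03d}" for i in range(n_genes)]
    classes = ("iugr_only", "pe_only", "equal", "equal_reversed")
    effect_class, magnitude, sign = {}, {}, {}
    mags = np.linspace(1.0, 3.0, per_class)
    pos = 0
    for cls in classes:
        for j in range(per_class):
            g = genes[pos]
            effect_class[g] = cls
            magnitude[g] = float(mags[j])
            sign[g] = 1 if j % 2 == 0 else -1
            pos += 1
    return SimulationConfig(
        genes=genes,
        effect_class=effect_class,
        effect_magnitude=magnitude,
        effect_sign=sign,
        noise_sd=noise_sd,
        seed=seed,
    )


def cohort_communities(config: SimulationConfig) -> dict[str, list[str]]:
    """Planted interaction communities = the non-null effect classes."""
    out: dict[str, list[str]] = {}
    for gene in config.genes:
        cls = config.gene_class(gene)
        if cls != "null":
            out.setdefault(cls, []).append(gene)
    return out


# ---------------------------------------------------------------------------
# Fixture bundle + config round trip
# ---------------------------------------------------------------------------

def write_fixture_bundle(config: SimulationConfig, out_dir: str | Path) -> dict[str, Path]:
    """Write the complete tab-separated fixture bundle; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    studies, truth = simulate_studies(config)
    ann_rows = []
    for study in studies:
        p = out / f"study_{study.study_id}.tsv"
        write_matrix(study.matrix, p)
        paths[f"study_{study.study_id}"] = p
        for sample in study.samples:
            ann_rows.append((sample, study.groups[sample], study.study_id))
    ann = pd.DataFrame(ann_rows, columns=["sample_id", "group", "study_id"])
    paths["annotations"] = out / "sample_annotations.tsv"
    write_results_table(ann, paths["annotations"])

    ct, qc, _ = simulate_ct_table(config)
    paths["ct_table"] = out / "ct_table.tsv"
    ct_out = ct.copy()
    gene_cols = [c for c in ct.columns if c not in ("sample_id", "group", "replicate")]
    ct_out[gene_cols] = ct_out[gene_cols].round(6)
    write_results_table(ct_out, paths["ct_table"])
    paths["qc_table"] = out / "qc_table.tsv"
    write_results_table(qc.round(6), paths["qc_table"])

    paths["truth"] = out / "truth.tsv"
    write_results_table(truth.table.reset_index(), paths["truth"])

    flags = pd.DataFrame({"gene": config.genes,
                          "placenta_annotated": ["true"] * len(config.genes)})
    paths["gene_annotations"] = out / "gene_annotations.tsv"
    write_results_table(flags, paths["gene_annotations"])

    edges = simulate_interaction_graph(
        cohort_communities(config),
        rng=int(np.random.SeedSequence(
            entropy=config.seed, spawn_key=(12345,)).generate_state(1)[0] % (2**31)),
    )
    paths["interactions"] = out / "interactions.tsv"
    edges.to_csv(paths["interactions"], sep="\t", header=False, index=False)

    paths["config"] = out / "simulation_config.txt"
    write_config(config, paths["config"])
    return paths


def write_config(config: SimulationConfig, path: str | Path) -> None:
    """Serialize the full configuration as flat ``key<TAB>value`` text."""
    lines = [
        f"effect_size\t{config.effect_size!r}",
        f"noise_sd\t{config.noise_sd!r}",
        f"ct_baseline\t{config.ct_baseline!r}",
        f"n_replicates\t{config.n_replicates}",
        f"sample_offset_sd\t{config.sample_offset_sd!r}",
        f"qc_fail_fraction\t{config.qc_fail_fraction!r}",
        f"seed\t{config.seed}",
        f"reference_genes\t{','.join(config.reference_genes)}",
    ]
    for group, n in config.group_sizes.items():
        lines.append(f"group_size.{group}\t{n}")
    for d in config.study_designs:
        lines.append(f"study.{d.study_id}\t{d.n_control},{d.n_iugr},{d.n_pe}")
    for gene in config.genes:
        cls = config.gene_class(gene)
        mag = config.effect_magnitude.get(gene, config.effect_size)
        sign = config.effect_sign.get(gene, 1)
        lines.append(f"gene.{gene}\t{cls},{mag!r},{sign}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_config(path: str | Path) -> SimulationConfig:
    """Parse a configuration written by :func:`write_config` (exact round trip)."""
    scalars: dict[str, str] = {}
    group_sizes: dict[str, int] = {}
    designs: list[StudyDesign] = []
    genes: list[str] = []
    effect_class: dict[str, str] = {}
    magnitude: dict[str, float] = {}
    sign: dict[str, int] = {}
    for raw in Path(path).read_text().splitlines():
        if not raw.strip() or raw.startswith("#"):
            continue
        key, value = raw.split("\t", 1)
        if key.startswith("group_size."):
            group_sizes[key.removeprefix("group_size.")] = int(value)
        elif key.startswith("study."):
            nc, ni, npe = (int(v) for v in value.split(","))
            designs.append(StudyDesign(key.removeprefix("study."), nc, ni, npe))
        elif key.startswith("gene."):
            gene = key.removeprefix("gene.")
            cls, mag, sgn = value.split(",")
            genes.append(gene)
            if cls != "null":
                effect_class[gene] = cls
            magnitude[gene] = float(mag)
            sign[gene] = int(sgn)
        else:
            scalars[key] = value
    return SimulationConfig(
        genes=genes,
        effect_class=effect_class,
        effect_magnitude=magnitude,
        effect_sign=sign,
        effect_size=float(scalars["effect_size"]),
        noise_sd=float(scalars["noise_sd"]),
        group_sizes=group_sizes,
        study_designs=tuple(designs),
        reference_genes=tuple(scalars["reference_genes"].split(",")),
        ct_baseline=float(scalars["ct_baseline"]),
        n_replicates=int(scalars["n_replicates"]),
        sample_offset_sd=float(scalars["sample_offset_sd"]),
        qc_fail_fraction=float(scalars["qc_fail_fraction"]),
        seed=int(scalars["seed"]),
    )
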