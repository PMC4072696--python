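"""Simulation of two-condition expression studies with planted regulation.

The generator emulates the structure of a paired tumor/normal microarray
study: a large mRNA matrix and a smaller matched miRNA matrix on the log2
scale, Gaussian noise (arrays are approximately Gaussian after RMA-style
summarization), a planted differential-expression signal, and an optional
hidden subtype/batch factor (e.g. gene-fusion status) that can be partially
aligned with the condition to exercise surrogate-variable adjustment.  A
companion prior generator plants feed-forward loops of every subtype with
known coherence and consistency, plus decoy edges among null features, and
emits the full input bundle (priors, pathway graphs, gene sets, whitelist)
with a machine-readable ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from .types import (
    ACTIVATION,
    EV_BOTH,
    EV_PREDICTED,
    EV_VALIDATED,
    REPRESSION,
    ExpressionMatrix,
    GeneSet,
    PathwayGraph,
    PriorDB,
    RegulatoryEdge,
    SampleDesign,
    SchemaError,
)

PLANTED_PATHWAY = "PATHWAY_PLANTED"
DECOY_PATHWAY = "PATHWAY_NULL"


@dataclass
class SimulationConfig:
    """Study conditions for the simulator.

    Effect sizes are in log2 units.  ``batch_effect`` is the magnitude of the
    per-feature hidden-factor coefficient (sign random per feature, applied
    to every feature when non-zero); ``batch_alignment`` is the probability
    that a tumor sample carries the factor (normals carry it with the
    complementary probability), so 0.5 means unconfounded and 0.7 means a
    70%-condition-aligned factor.
    """

    n_genes: int = 2000
    n_mirnas: int = 40
    n_samples_per_condition: int = 20
    de_fraction_genes: float = 0.05
    de_fraction_mirnas: float = 0.3
    effect_size: float = 2.0
    noise_sd: float = 0.25
    batch_effect: float = 0.0
    batch_alignment: float = 0.5
    n_planted_per_subtype: int = 2
    n_planted_type3: int = 2
    n_decoy_edges: int = 30
    predictor_count_low: int = 2
    predictor_count_high: int = 8
    validated_probability: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_mirnas", "n_samples_per_condition"):
            if getattr(self, name) < 1:
                raise SchemaError(f"{name} must be positive")
        if not (0 <= self.batch_alignment <= 1):
            raise SchemaError("batch_alignment must lie in [0, 1]")
        if self.predictor_count_low < 2:
            raise SchemaError("predicted edges need at least 2 supporting algorithms")


@dataclass
class GroundTruth:
    """Planted structure recorded by the simulator."""

    de_genes: dict = field(default_factory=dict)  # gene -> +1/-1
    de_mirnas: dict = field(default_factory=dict)
    batch_mrna: list = field(default_factory=list)  # 0/1 per mRNA sample
    batch_mirna: list = field(default_factory=list)
    planted_loops: pd.DataFrame | None = None
    enriched_pathways: list = field(default_factory=list)


@dataclass
class SimulatedExpression:
    mrna: ExpressionMatrix
    mirna: ExpressionMatrix
    design_mrna: SampleDesign
    design_mirna: SampleDesign
    truth: GroundTruth


@dataclass
class SimulatedPriors:
    priordb: PriorDB
    gene_sets: list
    pathway_graphs: list
    whitelist: list


PLANTED_LOOP_COLUMNS = [
    "loop_type",
    "subtype",
    "coherence",
    "mirna",
    "tf_or_gene1",
    "mrna_or_gene2",
    "pathway_id",
    "consistent",
]


def _simulate_matrix(
    rng: np.random.Generator,
    feature_ids,
    kind: str,
    prefix: str,
    config: SimulationConfig,
    de_directions: dict,
    paired: bool,
) -> tuple:
    n = config.n_samples_per_condition
    if paired:
        sample_ids = [f"{prefix}{i + 1:02d}_N" for i in range(n)] + [
            f"{prefix}{i + 1:02d}_T" for i in range(n)
        ]
        pair_ids = [f"{prefix}{i + 1:02d}" for i in range(n)] * 2
    else:
        sample_ids = [f"{prefix}N{i + 1:02d}" for i in range(n)] + [
            f"{prefix}T{i + 1:02d}" for i in range(n)
        ]
        pair_ids = [""] * (2 * n)
    condition = ["normal"] * n + ["tumor"] * n

    baseline = rng.normal(7.0, 1.5, size=len(feature_ids))
    values = rng.normal(0.0, config.noise_sd, size=(len(feature_ids), 2 * n))
    values += baseline[:, None]

    is_tumor = np.array([c == "tumor" for c in condition])
    for i, fid in enumerate(feature_ids):
        d = de_directions.get(fid)
        if d:
            values[i, is_tumor] += d * config.effect_size

    # hidden subtype/batch factor
    p_batch = np.where(is_tumor, config.batch_alignment, 1.0 - config.batch_alignment)
    batch = (rng.random(2 * n) < p_batch).astype(int)
    if config.batch_effect != 0.0:
        coef = config.batch_effect * rng.choice([-1.0, 1.0], size=len(feature_ids))
        values += coef[:, None] * batch[None, :]

    frame = pd.DataFrame(values, index=pd.Index(feature_ids, name="feature_id"),
                         columns=sample_ids)
    matrix = ExpressionMatrix(frame, kind)
    subtype = ["fusion_pos" if b else "fusion_neg" for b in batch]
    design = SampleDesign(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "condition": condition,
                "subtype": subtype,
                "pair_id": pair_ids,
            }
        )
    )
    return matrix, design, batch.tolist()


def _pick_de(rng: np.random.Generator, ids, fraction: float) -> dict:
    n_de = int(round(len(ids) * fraction))
    chosen = sorted(rng.choice(len(ids), size=n_de, replace=False))
    # alternate directions so both signs are always available for planting
    return {ids[j]: (1 if k % 2 == 0 else -1) for k, j in enumerate(chosen)}


def simulate_expression(config: SimulationConfig) -> SimulatedExpression:
    """Generate the mRNA and miRNA matrices, designs, and expression ground truth."""
    rng = np.random.default_rng(config.seed)
    genes = [f"G{i + 1:04d}" for i in range(config.n_genes)]
    mirnas = [f"mir-{i + 1:03d}" for i in range(config.n_mirnas)]

    de_genes = {} if config.effect_size == 0 else _pick_de(rng, genes, config.de_fraction_genes)
    de_mirnas = {} if config.effect_size == 0 else _pick_de(rng, mirnas, config.de_fraction_mirnas)

    mrna, design_mrna, batch_mrna = _simulate_matrix(
        rng, genes, "mRNA", "", config, de_genes, paired=False
    )
    mirna, design_mirna, batch_mirna = _simulate_matrix(
        rng, mirnas, "miRNA", "P", config, de_mirnas, paired=True
    )
    truth = GroundTruth(
        de_genes=de_genes,
        de_mirnas=de_mirnas,
        batch_mrna=batch_mrna,
        batch_mirna=batch_mirna,
        planted_loops=pd.DataFrame(columns=PLANTED_LOOP_COLUMNS),
    )
    return SimulatedExpression(mrna, mirna, design_mrna, design_mirna, truth)


# (loop_type, subtype, coherence) -> (tf->mRNA sign, tf->miRNA sign or None)
SUBTYPE_SIGNS = {
    ("I", "none", "coherent"): (ACTIVATION, None),
    ("I", "none", "incoherent"): (REPRESSION, None),
    ("II", "A", "coherent"): (ACTIVATION, REPRESSION),
    ("II", "A", "incoherent"): (ACTIVATION, ACTIVATION),
    ("II", "B", "coherent"): (REPRESSION, ACTIVATION),
    ("II", "B", "incoherent"): (REPRESSION, REPRESSION),
}


class _Pools:
    """Deterministic draws of unused DE features by direction."""

    def __init__(self, directions: dict, label: str):
        self.up = [f for f in sorted(directions) if directions[f] == 1]
        self.down = [f for f in sorted(directions) if directions[f] == -1]
        self.label = label

    def take(self, direction: int) -> str:
        pool = self.up if direction == 1 else self.down
        if not pool:
            raise SchemaError(
                f"not enough {'up' if direction == 1 else 'down'}-regulated "
                f"{self.label} features to plant the requested loops"
            )
        return pool.pop(0)


def _mirna_edge(rng, config, mirna, gene, evidence_cycle) -> RegulatoryEdge:
    evidence = evidence_cycle[0]
    evidence_cycle.append(evidence_cycle.pop(0))
    if evidence == EV_VALIDATED:
        n_pred = 0
    else:
        n_pred = int(rng.integers(config.predictor_count_low, config.predictor_count_high + 1))
    return RegulatoryEdge(
        regulator_id=mirna,
        regulator_kind="miRNA",
        target_id=gene,
        target_kind="gene",
        regulation=REPRESSION,
        evidence=evidence,
        n_predictors=n_pred,
    )


def simulate_priors(config: SimulationConfig, truth: GroundTruth) -> SimulatedPriors:
    """Plant loops of every subtype among DE regulators, plus decoy edges.

    Planted loops alternate the consistency designation: consistent loops get
    node directions that satisfy both the regulator-regulator edge relation
    and miRNA-target anti-correlation; inconsistent loops keep the former but
    break the latter.  Decoy edges connect non-DE features only, so a clean
    run reconstructs exactly the planted set.  The planted pathway contains
    mostly DE genes so the set-enrichment stage flags it.
    """
    rng = np.random.default_rng(config.seed + 1)
    gene_pool = _Pools(truth.de_genes, "gene")
    mirna_dirs = truth.de_mirnas
    de_mirna_ids = sorted(mirna_dirs)
    if not de_mirna_ids and (config.n_planted_per_subtype or config.n_planted_type3):
        raise SchemaError("no DE miRNAs available for loop planting")

    tf_gene: list = []
    tf_mirna: list = []
    mirna_gene: list = []
    planted_rows: list = []
    evidence_cycle = [EV_BOTH, EV_PREDICTED, EV_VALIDATED]
    mirna_cursor = 0

    specs = []
    for key in SUBTYPE_SIGNS:
        for j in range(config.n_planted_per_subtype):
            specs.append((key, j % 2 == 0))  # alternate consistent/inconsistent

    for (loop_type, subtype, coherence), consistent in specs:
        s1, s2 = SUBTYPE_SIGNS[(loop_type, subtype, coherence)]
        mirna = de_mirna_ids[mirna_cursor % len(de_mirna_ids)]
        mirna_cursor += 1
        dir_m = mirna_dirs[mirna]
        if loop_type == "I":
            dir_tf = -dir_m
        else:
            dir_tf = (1 if s2 == ACTIVATION else -1) * dir_m
        dir_g = -dir_m if consistent else dir_m
        tf = gene_pool.take(dir_tf)
        gene = gene_pool.take(dir_g)

        tf_gene.append(
            RegulatoryEdge(tf, "TF", gene, "gene", s1)
        )
        mirna_gene.append(_mirna_edge(rng, config, mirna, gene, evidence_cycle))
        if loop_type == "I":
            mirna_gene.append(_mirna_edge(rng, config, mirna, tf, evidence_cycle))
        else:
            tf_mirna.append(RegulatoryEdge(tf, "TF", mirna, "miRNA", s2))
        planted_rows.append(
            (loop_type, subtype, coherence, mirna, tf, gene, "",
             "consistent" if consistent else "inconsistent")
        )

    # ------------------------------------------------------------------
    # planted pathway with Type III loops
    pathway_graphs: list = []
    if config.n_planted_type3:
        endpoints = []
        for j in range(config.n_planted_type3):
            mirna = de_mirna_ids[j % len(de_mirna_ids)]
            g1 = gene_pool.take(1)
            g2 = gene_pool.take(-1)
            g1, g2 = sorted((g1, g2))
            endpoints.append((mirna, g1, g2))
            mirna_gene.append(_mirna_edge(rng, config, mirna, g1, evidence_cycle))
            mirna_gene.append(_mirna_edge(rng, config, mirna, g2, evidence_cycle))
            planted_rows.append(("III", "none", "none", mirna, g1, g2, PLANTED_PATHWAY, ""))
        filler_de = [gene_pool.take(1 if j % 2 == 0 else -1) for j in range(6)]
        all_genes = sorted(truth.de_genes)
        non_de = [g for g in sorted(set(_all_gene_ids(config)) - set(all_genes))][:4]
        nodes = {g for _, g1, g2 in endpoints for g in (g1, g2)} | set(filler_de) | set(non_de)
        edges = [(g1, g2, "direct") for _, g1, g2 in endpoints]
        for a, b in zip(filler_de, filler_de[1:]):
            edges.append((a, b, "direct"))
        if len(filler_de) >= 2:
            # an indirect interaction that must never yield a loop
            edges.append((filler_de[0], filler_de[-1], "indirect"))
        if non_de:
            edges.append((filler_de[0], non_de[0], "direct"))
        pathway_graphs.append(PathwayGraph(PLANTED_PATHWAY, nodes, edges))
        truth.enriched_pathways = [PLANTED_PATHWAY]

    # ------------------------------------------------------------------
    # decoy edges among non-DE features and a decoy pathway
    if config.n_decoy_edges:
        all_genes = _all_gene_ids(config)
        all_mirnas = [f"mir-{i + 1:03d}" for i in range(config.n_mirnas)]
        used = {e.target_id for e in mirna_gene} | {e.regulator_id for e in tf_gene}
        null_genes = [g for g in all_genes if g not in truth.de_genes and g not in used]
        null_mirnas = [m for m in all_mirnas if m not in truth.de_mirnas]
        rng.shuffle(null_genes)
        gi = iter(null_genes)
        seen_tf_pairs = set()
        for k in range(config.n_decoy_edges):
            try:
                tf = next(gi)
                gene = next(gi)
            except StopIteration:
                break
            regulation = ACTIVATION if k % 2 == 0 else REPRESSION
            tf_gene.append(RegulatoryEdge(tf, "TF", gene, "gene", regulation))
            if null_mirnas:
                mirna = null_mirnas[k % len(null_mirnas)]
                mirna_gene.append(_mirna_edge(rng, config, mirna, gene, evidence_cycle))
                if (tf, mirna) not in seen_tf_pairs:
                    tf_mirna.append(RegulatoryEdge(tf, "TF", mirna, "miRNA", regulation))
                    seen_tf_pairs.add((tf, mirna))
        decoy_nodes = [g for g in all_genes if g not in truth.de_genes][-8:]
        decoy_edges = [
            (a, b, "direct") for a, b in zip(decoy_nodes, decoy_nodes[1:])
        ]
        if decoy_edges:
            pathway_graphs.append(
                PathwayGraph(DECOY_PATHWAY, set(decoy_nodes), decoy_edges)
            )

    truth.planted_loops = pd.DataFrame(planted_rows, columns=PLANTED_LOOP_COLUMNS)

    whitelist = sorted(set(de_mirna_ids))
    priordb = PriorDB(tf_gene=tf_gene, tf_mirna=tf_mirna, mirna_gene=mirna_gene)

    gene_sets = []
    targets_by_tf: dict = {}
    for e in tf_gene:
        targets_by_tf.setdefault(e.regulator_id, set()).add(e.target_id)
    for tf in sorted(targets_by_tf):
        gene_sets.append(GeneSet(tf, "TF", frozenset(targets_by_tf[tf])))
    for g in pathway_graphs:
        gene_sets.append(GeneSet(g.pathway_id, "pathway", frozenset(g.nodes)))

    return SimulatedPriors(priordb, gene_sets, pathway_graphs, whitelist)


def _all_gene_ids(config: SimulationConfig) -> list:
    return [f"G{i + 1:04d}" for i in range(config.n_genes)]


def simulate_bundle(config: SimulationConfig) -> tuple:
    """Convenience wrapper: expression plus priors in one call."""
    sim = simulate_expression(config)
    priors = simulate_priors(config, sim.truth)
    return sim, priors


def write_bundle(sim: SimulatedExpression, priors: SimulatedPriors, outdir) -> Path:
    """Write the complete input bundle plus ground truth and a pipeline config."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mio.write_expression(sim.mrna, outdir / "mrna.tsv")
    mio.write_expression(sim.mirna, outdir / "mirna.tsv")
    mio.write_design(sim.design_mrna, outdir / "mrna_design.tsv")
    mio.write_design(sim.design_mirna, outdir / "mirna_design.tsv")
    mio.write_tf_table(priors.priordb.tf_gene, outdir / "tf_gene.tsv", "target_gene")
    mio.write_tf_table(priors.priordb.tf_mirna, outdir / "tf_mirna.tsv", "target_mirna")
    mio.write_mirna_tables(
        priors.priordb.mirna_gene,
        outdir / "mirna_targets_predicted.tsv",
        outdir / "mirna_targets_validated.tsv",
    )
    mio.write_pathway_edges(priors.pathway_graphs, outdir / "pathway_edges.tsv")
    mio.write_gmt(priors.gene_sets, outdir / "gene_sets.gmt")
    mio.write_whitelist(priors.whitelist, outdir / "whitelist.txt")

    truth = sim.truth
    truth_doc = {
        "de_genes": truth.de_genes,
        "de_mirnas": truth.de_mirnas,
        "batch_mrna": truth.batch_mrna,
        "batch_mirna": truth.batch_mirna,
        "planted_loops": truth.planted_loops.to_dict(orient="records"),
        "enriched_pathways": truth.enriched_pathways,
    }
    with open(outdir / "ground_truth.json", "w", encoding="utf-8") as fh:
        json.dump(truth_doc, fh, indent=2, sort_keys=True)

    config_doc = {
        "inputs": {
            "mrna": "mrna.tsv",
            "mirna": "mirna.tsv",
            "mrna_design": "mrna_design.tsv",
            "mirna_design": "mirna_design.tsv",
            "tf_gene": "tf_gene.tsv",
            "tf_mirna": "tf_mirna.tsv",
            "mirna_targets_predicted": "mirna_targets_predicted.tsv",
            "mirna_targets_validated": "mirna_targets_validated.tsv",
            "pathway_edges": "pathway_edges.tsv",
            "whitelist": "whitelist.txt",
        },
        "params": {"seed": 0},
        "output_dir": "results",
    }
    with open(outdir / "config.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(config_doc, fh, sort_keys=True)
    return outdir


def read_ground_truth(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    doc["planted_loops"] = pd.DataFrame(
        doc["planted_loops"], columns=PLANTED_LOOP_COLUMNS
    )
    return doc
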