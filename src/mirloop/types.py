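"""Shared domain types for the loop-inference pipeline.

Expression values are assumed to be on the log2 scale throughout (RMA-like
summaries for microarray data).  miRNA identifiers and gene/TF identifiers
live in disjoint namespaces; a transcription factor appears in the mRNA
matrix under its gene id.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MRNA = "mRNA"
MIRNA = "miRNA"
FEATURE_KINDS = (MRNA, MIRNA)

ACTIVATION = "activation"
REPRESSION = "repression"
REGULATION_TOKENS = (ACTIVATION, REPRESSION)

EV_PREDICTED = "predicted"
EV_VALIDATED = "validated"
EV_BOTH = "both"
EVIDENCE_TOKENS = (EV_PREDICTED, EV_VALIDATED, EV_BOTH)


class SchemaError(ValueError):
    """An input violates a structural invariant (duplicate ids, bad tokens...)."""


class ParseError(ValueError):
    """A cell of an input file could not be parsed; the message names it."""


def sign_of(regulation: str) -> int:
    """Map a regulation token to its arithmetic sign (+1 activation, -1 repression)."""
    if regulation == ACTIVATION:
        return 1
    if regulation == REPRESSION:
        return -1
    raise SchemaError(f"unknown regulation token {regulation!r}")


@dataclass
class ExpressionMatrix:
    """A features x samples matrix of log2 expression values.

    ``values`` is indexed by feature id with one column per sample id.
    """

    values: pd.DataFrame
    feature_kind: str

    def __post_init__(self) -> None:
        if self.feature_kind not in FEATURE_KINDS:
            raise SchemaError(f"feature_kind must be one of {FEATURE_KINDS}")
        idx = self.values.index
        cols = self.values.columns
        if idx.duplicated().any():
            dups = idx[idx.duplicated()].unique().tolist()
            raise SchemaError(f"duplicate feature ids: {dups}")
        if cols.duplicated().any():
            dups = cols[cols.duplicated()].unique().tolist()
            raise SchemaError(f"duplicate sample ids: {dups}")
        arr = self.values.to_numpy()
        if arr.size and not np.isfinite(arr).all():
            r, c = np.argwhere(~np.isfinite(arr))[0]
            raise ParseError(
                f"non-finite value at feature {idx[r]!r}, sample {cols[c]!r}"
            )

    @property
    def feature_ids(self) -> list:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple:
        return self.values.shape


@dataclass
class SampleDesign:
    """Sample annotations: condition (normal/tumor), subtype label, optional pairing."""

    table: pd.DataFrame  # columns: sample_id, condition, subtype, pair_id

    def __post_init__(self) -> None:
        required = ["sample_id", "condition", "subtype", "pair_id"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise SchemaError(f"design table missing columns {missing}")
        if self.table["sample_id"].duplicated().any():
            raise SchemaError("duplicate sample ids in design table")
        bad = set(self.table["condition"]) - {"normal", "tumor"}
        if bad:
            raise SchemaError(f"unknown condition labels {sorted(bad)}")
        counts = self.table["condition"].value_counts()
        if counts.get("normal", 0) < 2 or counts.get("tumor", 0) < 2:
            raise SchemaError("need at least 2 samples per condition")

    def for_samples(self, sample_ids) -> "SampleDesign":
        sub = self.table.set_index("sample_id").reindex(sample_ids)
        if sub["condition"].isna().any():
            absent = [s for s in sample_ids if s not in set(self.table["sample_id"])]
            raise SchemaError(f"samples missing from design table: {absent}")
        return SampleDesign(sub.reset_index())

    def condition_indicator(self, sample_ids) -> np.ndarray:
        """0/1 vector over ``sample_ids`` with tumor = 1."""
        cond = self.table.set_index("sample_id")["condition"].reindex(sample_ids)
        if cond.isna().any():
            absent = list(cond.index[cond.isna()])
            raise SchemaError(f"samples missing from design table: {absent}")
        return (cond == "tumor").to_numpy(dtype=float)

    def pair_labels(self, sample_ids) -> list:
        tab = self.table.set_index("sample_id").reindex(sample_ids)
        return list(tab["pair_id"].fillna(""))


@dataclass(frozen=True)
class GeneSet:
    set_id: str
    index_kind: str  # "TF" | "miRNA" | "pathway"
    members: frozenset

    def __post_init__(self) -> None:
        if not self.members:
            raise SchemaError(f"gene set {self.set_id!r} has no members")


@dataclass(frozen=True)
class RegulatoryEdge:
    """A typed regulator -> target edge with regulation sign and evidence."""

    regulator_id: str
    regulator_kind: str  # "TF" | "miRNA"
    target_id: str
    target_kind: str  # "gene" | "miRNA"
    regulation: str  # activation | repression
    evidence: str = EV_PREDICTED
    n_predictors: int = 0

    def __post_init__(self) -> None:
        if self.regulation not in REGULATION_TOKENS:
            raise SchemaError(f"unknown regulation token {self.regulation!r}")
        if self.evidence not in EVIDENCE_TOKENS:
            raise SchemaError(f"unknown evidence token {self.evidence!r}")
        if self.regulator_kind == "miRNA" and self.regulation != REPRESSION:
            raise SchemaError("miRNA-regulator edges are always repressing")
        if self.n_predictors < 0:
            raise SchemaError("n_predictors must be non-negative")


def _check_no_duplicate_pairs(edges, table_name: str) -> None:
    seen = set()
    for e in edges:
        key = (e.regulator_id, e.target_id)
        if key in seen:
            raise SchemaError(f"duplicate edge {key} in {table_name}")
        seen.add(key)


@dataclass
class PriorDB:
    """Regulatory-prior tables: TF->gene, TF->miRNA and miRNA->gene edges."""

    tf_gene: list = field(default_factory=list)
    tf_mirna: list = field(default_factory=list)
    mirna_gene: list = field(default_factory=list)

    def __post_init__(self) -> None:
        _check_no_duplicate_pairs(self.tf_gene, "tf_gene")
        _check_no_duplicate_pairs(self.tf_mirna, "tf_mirna")
        _check_no_duplicate_pairs(self.mirna_gene, "mirna_gene")

    @staticmethod
    def _frame(edges) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (e.regulator_id, e.target_id, e.regulation, e.evidence, e.n_predictors)
                for e in edges
            ],
            columns=["regulator", "target", "regulation", "evidence", "n_predictors"],
        )

    def tf_gene_frame(self) -> pd.DataFrame:
        return self._frame(self.tf_gene)

    def tf_mirna_frame(self) -> pd.DataFrame:
        return self._frame(self.tf_mirna)

    def mirna_gene_frame(self) -> pd.DataFrame:
        return self._frame(self.mirna_gene)


@dataclass
class PathwayGraph:
    """Undirected gene-gene interaction map for one signaling pathway."""

    pathway_id: str
    nodes: set
    edges: list  # of (gene1, gene2, effect) with gene1 < gene2, effect direct|indirect

    def __post_init__(self) -> None:
        canon = []
        for g1, g2, effect in self.edges:
            if g1 == g2:
                raise SchemaError(
                    f"self-edge {g1!r} in pathway {self.pathway_id!r}"
                )
            if effect not in ("direct", "indirect"):
                raise SchemaError(f"unknown edge effect {effect!r}")
            if g1 not in self.nodes or g2 not in self.nodes:
                raise SchemaError(
                    f"edge ({g1}, {g2}) endpoints missing from pathway nodes"
                )
            a, b = sorted((g1, g2))
            canon.append((a, b, effect))
        self.edges = canon


@dataclass
class PipelineConfig:
    """Tunable thresholds of the pipeline.

    fdr_de: FDR level for per-transcript differential-expression calls.
    fdr_gsea: FDR level for the set-enrichment stage.
    min_set_size: minimum size of a miRNA validated-target gene set.
    min_predictors: minimum number of sequence-based predictors supporting a
        predicted miRNA-target edge.
    fc_threshold: fold change for the reporting filter (applied as
        2**delta >= fc or <= 1/fc).
    """

    fdr_de: float = 0.05
    fdr_gsea: float = 0.25
    min_set_size: int = 8
    min_predictors: int = 2
    fc_threshold: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.fdr_de < 1) or not (0 < self.fdr_gsea < 1):
            raise SchemaError("FDR thresholds must lie in (0, 1)")
        if self.min_set_size < 1:
            raise SchemaError("min_set_size must be >= 1")
        if self.min_predictors < 1:
            raise SchemaError("min_predictors must be >= 1")
        if self.fc_threshold < 1:
            raise SchemaError("fc_threshold must be >= 1")
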