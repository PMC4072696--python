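"""Readers and writers for every file format the pipeline touches.

All tables are UTF-8 TSV with a header row.  Gene sets use the standard GMT
interchange format (set id, description, then one member per column).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    EV_BOTH,
    EV_PREDICTED,
    EV_VALIDATED,
    REGULATION_TOKENS,
    REPRESSION,
    ExpressionMatrix,
    GeneSet,
    ParseError,
    PathwayGraph,
    PipelineConfig,
    PriorDB,
    RegulatoryEdge,
    SampleDesign,
    SchemaError,
)


# ---------------------------------------------------------------------------
# expression matrices


def read_expression(path, feature_kind: str) -> ExpressionMatrix:
    """Read a features x samples TSV (first column feature ids, header sample ids)."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    sample_ids = header[1:]
    if len(set(sample_ids)) != len(sample_ids):
        dups = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
        raise SchemaError(f"duplicate sample ids in {path.name}: {dups}")
    raw = pd.read_csv(
        path, sep="\t", index_col=0, dtype=str, keep_default_na=False, na_values=[]
    )
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = np.argwhere(numeric.isna().to_numpy())
    if bad.size:
        r, c = bad[0]
        raise ParseError(
            f"non-numeric cell {raw.iat[r, c]!r} at feature {raw.index[r]!r}, "
            f"sample {raw.columns[c]!r} in {path.name}"
        )
    numeric.index.name = "feature_id"
    return ExpressionMatrix(numeric.astype(float), feature_kind)


def write_expression(matrix: ExpressionMatrix, path) -> None:
    out = matrix.values.copy()
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t")


def read_design(path) -> SampleDesign:
    tab = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, na_values=[])
    if "pair_id" not in tab.columns:
        tab["pair_id"] = ""
    if "subtype" not in tab.columns:
        tab["subtype"] = "unknown"
    return SampleDesign(tab)


def write_design(design: SampleDesign, path) -> None:
    design.table.to_csv(path, sep="\t", index=False)


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample column onto the common per-rank across-sample means.

    Ties within a column receive the mean of the reference values over the
    tied ranks, so the operation is idempotent.
    """
    vals = matrix.values.to_numpy(dtype=float)
    n_feat, n_samp = vals.shape
    if n_samp < 1:
        raise SchemaError("need at least one sample")
    reference = np.sort(vals, axis=0).mean(axis=1)
    out = np.empty_like(vals)
    for j in range(n_samp):
        col = vals[:, j]
        order = np.argsort(col, kind="mergesort")
        assigned = np.empty(n_feat)
        assigned[order] = reference
        # average the reference over tied observed values
        s = pd.Series(assigned)
        out[:, j] = s.groupby(pd.Series(col)).transform("mean").to_numpy()
    frame = pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)
    return ExpressionMatrix(frame, matrix.feature_kind)


# ---------------------------------------------------------------------------
# regulatory priors


def _read_tf_table(path, target_kind: str) -> list:
    tab = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    tab.columns = [c.strip() for c in tab.columns]
    reg_col = tab.columns[0]
    tgt_col = tab.columns[1]
    edges = {}
    for _, row in tab.iterrows():
        regulation = row["regulation"]
        if regulation not in REGULATION_TOKENS:
            raise SchemaError(
                f"unknown regulation token {regulation!r} in {Path(path).name}"
            )
        key = (row[reg_col], row[tgt_col])
        prev = edges.get(key)
        if prev is not None and prev.regulation != regulation:
            raise SchemaError(
                f"conflicting regulation for edge {key} in {Path(path).name}"
            )
        edges[key] = RegulatoryEdge(
            regulator_id=row[reg_col],
            regulator_kind="TF",
            target_id=row[tgt_col],
            target_kind=target_kind,
            regulation=regulation,
        )
    return list(edges.values())


def read_priors(
    tf_gene_path,
    tf_mirna_path,
    mirna_pred_path,
    mirna_valid_path,
    config: PipelineConfig,
) -> PriorDB:
    """Load the four prior tables and merge miRNA-target evidence.

    Predicted miRNA->gene edges supported by fewer than ``config.min_predictors``
    sequence-based algorithms are dropped; pairs present in both the predicted
    and validated tables get evidence "both"; validated-only pairs are retained
    with evidence "validated" (and n_predictors possibly 0).
    """
    tf_gene = _read_tf_table(tf_gene_path, "gene")
    tf_mirna = _read_tf_table(tf_mirna_path, "miRNA")

    pred = pd.read_csv(mirna_pred_path, sep="\t", dtype=str, keep_default_na=False)
    predicted = {}
    for _, row in pred.iterrows():
        try:
            n_pred = int(row["n_predictors"])
        except ValueError as exc:
            raise ParseError(
                f"non-integer predictor count {row['n_predictors']!r} for "
                f"({row.iloc[0]}, {row.iloc[1]})"
            ) from exc
        key = (row.iloc[0], row.iloc[1])
        predicted[key] = max(n_pred, predicted.get(key, 0))

    valid = pd.read_csv(mirna_valid_path, sep="\t", dtype=str, keep_default_na=False)
    validated = {(row.iloc[0], row.iloc[1]) for _, row in valid.iterrows()}

    mirna_gene = []
    kept_pred = {
        k: n for k, n in predicted.items() if n >= config.min_predictors
    }
    for key in sorted(set(kept_pred) | validated):
        mirna, gene = key
        if key in kept_pred and key in validated:
            evidence = EV_BOTH
        elif key in kept_pred:
            evidence = EV_PREDICTED
        else:
            evidence = EV_VALIDATED
        mirna_gene.append(
            RegulatoryEdge(
                regulator_id=mirna,
                regulator_kind="miRNA",
                target_id=gene,
                target_kind="gene",
                regulation=REPRESSION,
                evidence=evidence,
                n_predictors=kept_pred.get(key, predicted.get(key, 0)),
            )
        )
    return PriorDB(tf_gene=tf_gene, tf_mirna=tf_mirna, mirna_gene=mirna_gene)


def write_tf_table(edges, path, target_col: str) -> None:
    rows = [(e.regulator_id, e.target_id, e.regulation) for e in edges]
    pd.DataFrame(rows, columns=["tf_id", target_col, "regulation"]).to_csv(
        path, sep="\t", index=False
    )


def write_mirna_tables(edges, predicted_path, validated_path) -> None:
    """Split merged miRNA->gene edges back into the two on-disk tables."""
    pred_rows = []
    valid_rows = []
    for e in edges:
        if e.evidence in (EV_PREDICTED, EV_BOTH):
            pred_rows.append((e.regulator_id, e.target_id, e.n_predictors))
        if e.evidence in (EV_VALIDATED, EV_BOTH):
            valid_rows.append((e.regulator_id, e.target_id))
    pd.DataFrame(
        pred_rows, columns=["mirna_id", "target_gene", "n_predictors"]
    ).to_csv(predicted_path, sep="\t", index=False)
    pd.DataFrame(valid_rows, columns=["mirna_id", "target_gene"]).to_csv(
        validated_path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# gene sets and pathways


def read_gmt(path) -> list:
    sets = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3 or not any(f.strip() for f in fields[2:]):
                raise SchemaError(
                    f"gene set on line {lineno} of {Path(path).name} has no members"
                )
            set_id = fields[0]
            kind = fields[1] if fields[1] in ("TF", "miRNA", "pathway") else "pathway"
            members = frozenset(f for f in fields[2:] if f.strip())
            sets.append(GeneSet(set_id=set_id, index_kind=kind, members=members))
    return sets


def write_gmt(sets, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gs in sets:
            fh.write("\t".join([gs.set_id, gs.index_kind] + sorted(gs.members)) + "\n")


def read_pathway_edges(path) -> list:
    """Read a `pathway_id, gene1, gene2, effect` TSV into PathwayGraph objects."""
    tab = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    graphs = {}
    for _, row in tab.iterrows():
        pid = row["pathway_id"]
        entry = graphs.setdefault(pid, {"nodes": set(), "edges": []})
        entry["nodes"].update([row["gene1"], row["gene2"]])
        entry["edges"].append((row["gene1"], row["gene2"], row["effect"]))
    return [
        PathwayGraph(pathway_id=pid, nodes=entry["nodes"], edges=entry["edges"])
        for pid, entry in sorted(graphs.items())
    ]


def write_pathway_edges(graphs, path) -> None:
    rows = []
    for g in graphs:
        for g1, g2, effect in g.edges:
            rows.append((g.pathway_id, g1, g2, effect))
    pd.DataFrame(rows, columns=["pathway_id", "gene1", "gene2", "effect"]).to_csv(
        path, sep="\t", index=False
    )


def read_whitelist(path) -> list:
    with open(path, encoding="utf-8") as fh:
        return [line.strip() for line in fh if line.strip()]


def write_whitelist(mirna_ids, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for mid in mirna_ids:
            fh.write(mid + "\n")
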