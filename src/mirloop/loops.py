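"""Construction of three-node regulatory loops from restricted priors.

Type I feed-forward loops place the miRNA upstream: it represses both a TF
transcript and an mRNA the TF regulates.  Type II loops place the TF
upstream: it regulates a miRNA and an mRNA the miRNA represses; subtype A/B
records whether the TF activates or represses the mRNA.  A loop is coherent
when the direct TF(or miRNA)->mRNA path and the two-edge indirect path carry
the same net sign (every miRNA->target edge contributes a minus).  Type III
loops pair a miRNA with two directly interacting genes on a significant
pathway map.
"""

from __future__ import annotations

import pandas as pd

from .types import PriorDB, SchemaError, sign_of

LOOP_COLUMNS = [
    "loop_type",
    "subtype",
    "coherence",
    "mirna",
    "tf_or_gene1",
    "mrna_or_gene2",
    "tf_mrna_sign",
    "tf_mirna_sign",
    "pathway_id",
    "evidence_tf_edge",
    "evidence_mrna_edge",
]


def empty_loops() -> pd.DataFrame:
    return pd.DataFrame(columns=LOOP_COLUMNS)


def restrict_priors(
    priordb: PriorDB,
    combined_mrna_ids,
    combined_mirna_ids,
    universe,
) -> PriorDB:
    """Keep only edges whose regulators are deregulated and targets measured."""
    mrna_ids = set(combined_mrna_ids)
    mirna_ids = set(combined_mirna_ids)
    universe = set(universe)
    tf_gene = [
        e for e in priordb.tf_gene if e.regulator_id in mrna_ids and e.target_id in universe
    ]
    tf_mirna = [
        e
        for e in priordb.tf_mirna
        if e.regulator_id in mrna_ids and e.target_id in mirna_ids
    ]
    mirna_gene = [
        e
        for e in priordb.mirna_gene
        if e.regulator_id in mirna_ids and e.target_id in universe
    ]
    return PriorDB(tf_gene=tf_gene, tf_mirna=tf_mirna, mirna_gene=mirna_gene)


def classify_subtype(
    loop_type: str, tf_to_mrna_sign: str, tf_to_mirna_sign: str | None = None
) -> tuple:
    """Return (subtype, coherence) for a loop from its TF edge signs.

    The direct and indirect regulator->mRNA paths are compared as sign
    products; a miRNA->target edge always contributes -1.
    """
    s1 = sign_of(tf_to_mrna_sign)
    if loop_type == "I":
        if tf_to_mirna_sign is not None:
            raise SchemaError("Type I loops have no TF->miRNA edge")
        # direct path miRNA -| mRNA = -1; indirect miRNA -| TF -> mRNA = -s1
        coherence = "coherent" if s1 == 1 else "incoherent"
        return "none", coherence
    if loop_type == "II":
        if tf_to_mirna_sign is None:
            raise SchemaError("Type II loops require a TF->miRNA edge sign")
        s2 = sign_of(tf_to_mirna_sign)
        subtype = "A" if s1 == 1 else "B"
        # direct path TF -> mRNA = s1; indirect TF -> miRNA -| mRNA = -s2
        coherence = "coherent" if s1 == -s2 else "incoherent"
        return subtype, coherence
    if loop_type == "III":
        return "none", "none"
    raise SchemaError(f"unknown loop type {loop_type!r}")


def _mirna_edge_lookup(mirna_gene_edges) -> dict:
    return {(e.regulator_id, e.target_id): e for e in mirna_gene_edges}


def _sorted_loops(rows) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=LOOP_COLUMNS)
    return df.sort_values(
        ["loop_type", "subtype", "coherence", "mirna", "tf_or_gene1", "mrna_or_gene2", "pathway_id"],
        kind="mergesort",
    ).reset_index(drop=True)


def build_type1(tf_gene_edges, mirna_gene_edges) -> pd.DataFrame:
    """Triplets (miRNA, TF, mRNA): the miRNA targets both the TF transcript and the mRNA."""
    by_mirna = {}
    for e in mirna_gene_edges:
        by_mirna.setdefault(e.regulator_id, {})[e.target_id] = e
    rows = []
    for tg in tf_gene_edges:
        tf, gene = tg.regulator_id, tg.target_id
        if tf == gene:
            continue  # self-regulation cannot close a three-node loop
        for mirna, targets in by_mirna.items():
            if tf in targets and gene in targets:
                subtype, coherence = classify_subtype("I", tg.regulation)
                rows.append(
                    (
                        "I",
                        subtype,
                        coherence,
                        mirna,
                        tf,
                        gene,
                        tg.regulation,
                        "",
                        "",
                        targets[tf].evidence,
                        targets[gene].evidence,
                    )
                )
    return _sorted_loops(rows) if rows else empty_loops()


def build_type2(tf_mirna_edges, tf_gene_edges, mirna_gene_edges) -> pd.DataFrame:
    """Triplets (miRNA, TF, mRNA): the TF regulates both the miRNA and an mRNA it targets."""
    mirna_targets = {}
    for e in mirna_gene_edges:
        mirna_targets.setdefault(e.regulator_id, {})[e.target_id] = e
    genes_by_tf = {}
    for e in tf_gene_edges:
        genes_by_tf.setdefault(e.regulator_id, []).append(e)
    rows = []
    for tm in tf_mirna_edges:
        tf, mirna = tm.regulator_id, tm.target_id
        targets = mirna_targets.get(mirna, {})
        for tg in genes_by_tf.get(tf, []):
            gene = tg.target_id
            if gene not in targets:
                continue
            subtype, coherence = classify_subtype("II", tg.regulation, tm.regulation)
            rows.append(
                (
                    "II",
                    subtype,
                    coherence,
                    mirna,
                    tf,
                    gene,
                    tg.regulation,
                    tm.regulation,
                    "",
                    "",
                    targets[gene].evidence,
                )
            )
    return _sorted_loops(rows) if rows else empty_loops()


def build_type3(
    pathway_graphs,
    mirna_gene_edges,
    expressed_genes,
    significant_pathways,
) -> pd.DataFrame:
    """Triplets (miRNA, G1, G2): direct pathway partners both targeted by the miRNA.

    Only pathways in ``significant_pathways`` contribute; indirect edges and
    unexpressed endpoint genes are excluded.  Gene pairs are canonically
    ordered, so each (miRNA, edge) yields one loop.
    """
    expressed = set(expressed_genes)
    significant = set(significant_pathways)
    targets_by_mirna = {}
    for e in mirna_gene_edges:
        targets_by_mirna.setdefault(e.regulator_id, {})[e.target_id] = e
    rows = []
    for graph in pathway_graphs:
        if graph.pathway_id not in significant:
            continue
        seen_pairs = set()
        for g1, g2, effect in graph.edges:
            if effect != "direct":
                continue
            if g1 not in expressed or g2 not in expressed:
                continue
            if (g1, g2) in seen_pairs:
                continue
            seen_pairs.add((g1, g2))
            for mirna, targets in targets_by_mirna.items():
                if g1 in targets and g2 in targets:
                    rows.append(
                        (
                            "III",
                            "none",
                            "none",
                            mirna,
                            g1,
                            g2,
                            "",
                            "",
                            graph.pathway_id,
                            targets[g1].evidence,
                            targets[g2].evidence,
                        )
                    )
    return _sorted_loops(rows) if rows else empty_loops()


def build_all_loops(
    restricted: PriorDB,
    pathway_graphs,
    expressed_genes,
    significant_pathways,
) -> pd.DataFrame:
    parts = [
        build_type1(restricted.tf_gene, restricted.mirna_gene),
        build_type2(restricted.tf_mirna, restricted.tf_gene, restricted.mirna_gene),
        build_type3(
            pathway_graphs, restricted.mirna_gene, expressed_genes, significant_pathways
        ),
    ]
    parts = [p for p in parts if not p.empty]
    if not parts:
        return empty_loops()
    return pd.concat(parts, ignore_index=True)
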