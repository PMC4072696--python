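"""Post-hoc analytics over scored loop tables.

These reproduce the usual reporting views: the distribution of FFL subtypes
split by consistency, per-miRNA transcriptome-deregulation attribution with
a cumulative curve, co-targeting overlaps between miRNA target sets, the
distinct miRNA-TF pairs behind the loops, and a general loop query helper.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd

from .scoring import GROUPS
from .types import ACTIVATION, SchemaError

FFL_SUBTYPES = [g for g in GROUPS if g != "III"]


def _ffl_only(loops: pd.DataFrame) -> pd.DataFrame:
    return loops[loops["loop_type"].isin(["I", "II"])]


def subtype_fractions(loops: pd.DataFrame) -> pd.DataFrame:
    """Fraction of all FFLs in each subtype x {consistent, inconsistent} cell."""
    ffl = _ffl_only(loops)
    if ffl.empty:
        raise SchemaError("no feed-forward loops: fractions are undefined")
    total = len(ffl)
    rows = []
    for group in FFL_SUBTYPES:
        for flag in ("consistent", "inconsistent"):
            n = int(((ffl["group"] == group) & (ffl["consistent"] == flag)).sum())
            rows.append((group, flag, n, n / total))
    return pd.DataFrame(rows, columns=["subtype", "consistency", "count", "fraction"])


def mirna_attribution(
    loops: pd.DataFrame,
    de_mrna: pd.DataFrame,
    mirna_directions: dict,
) -> tuple:
    """Percent of deregulated transcripts attributable to each miRNA's FFLs.

    For every miRNA, the distinct differentially expressed mRNAs appearing
    as its targets in any FFL are counted against the total number of DE
    mRNAs, split into consistent (miRNA and target anti-correlated) and
    inconsistent portions.  Returns ``(per_mirna, cumulative)`` where the
    cumulative curve ranks miRNAs by decreasing consistent percentage and
    counts each mRNA once.
    """
    de_ids = set(de_mrna.index)
    if not de_ids:
        raise SchemaError("empty DE mRNA list: attribution is undefined")
    de_dir = de_mrna["direction"].to_dict()
    ffl = _ffl_only(loops)
    targets = {}
    for _, row in ffl.iterrows():
        mirna = row["mirna"]
        gene = row["mrna_or_gene2"]
        if gene in de_ids:
            targets.setdefault(mirna, set()).add(gene)
    denom = len(de_ids)
    rows = []
    consistent_sets = {}
    for mirna in sorted(set(mirna_directions) | set(targets)):
        tset = targets.get(mirna, set())
        d_mirna = mirna_directions.get(mirna)
        cons = {g for g in tset if d_mirna is not None and de_dir[g] == -d_mirna}
        incons = tset - cons
        consistent_sets[mirna] = cons
        rows.append(
            (
                mirna,
                len(tset),
                100.0 * len(cons) / denom,
                100.0 * len(incons) / denom,
                100.0 * len(tset) / denom,
            )
        )
    per_mirna = pd.DataFrame(
        rows,
        columns=["mirna", "n_de_targets", "consistent_pct", "inconsistent_pct", "total_pct"],
    ).sort_values(
        ["consistent_pct", "mirna"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)

    seen_any: set = set()
    seen_cons: set = set()
    cum_rows = []
    for _, rec in per_mirna.iterrows():
        mirna = rec["mirna"]
        seen_any |= targets.get(mirna, set())
        seen_cons |= consistent_sets.get(mirna, set())
        cum_rows.append(
            (mirna, 100.0 * len(seen_any) / denom, 100.0 * len(seen_cons) / denom)
        )
    cumulative = pd.DataFrame(
        cum_rows, columns=["mirna", "cumulative_total_pct", "cumulative_consistent_pct"]
    )
    return per_mirna, cumulative


def cotargeting_overlap(mirna_ids, loops: pd.DataFrame) -> pd.DataFrame:
    """Counts of every non-empty intersection region of the miRNAs' target sets.

    Targets are the distinct mRNAs each miRNA pairs with across all FFLs.
    Regions are labeled by the subset of miRNAs that contain the target
    (exclusive regions, as in a Venn diagram); counts sum to the union size.
    """
    mirna_ids = list(mirna_ids)
    ffl = _ffl_only(loops)
    sets = {m: set() for m in mirna_ids}
    for _, row in ffl.iterrows():
        if row["mirna"] in sets:
            sets[row["mirna"]].add(row["mrna_or_gene2"])
    union = set().union(*sets.values()) if sets else set()
    membership: dict = {}
    for gene in union:
        key = tuple(m for m in mirna_ids if gene in sets[m])
        membership[key] = membership.get(key, 0) + 1
    rows = []
    for r in range(1, len(mirna_ids) + 1):
        for combo in combinations(mirna_ids, r):
            rows.append(("&".join(combo), len(combo), membership.get(combo, 0)))
    return pd.DataFrame(rows, columns=["region", "degree", "count"])


def extract_mirna_tf_pairs(loops: pd.DataFrame) -> pd.DataFrame:
    """Distinct (miRNA, TF) pairs behind the FFLs, categorized by interaction type.

    Type I pairs are miRNA-represses-TF; Type II pairs are TF-activates-miRNA
    or TF-represses-miRNA depending on the edge sign.  The consistency flag
    records whether the pair's own edge relation holds in the expression data
    in at least one loop (it is a property of the two nodes' directions, so
    it is constant across loops sharing the pair).
    """
    ffl = _ffl_only(loops)
    records: dict = {}
    for _, row in ffl.iterrows():
        if row["loop_type"] == "I":
            category = "miRNA-represses-TF"
            edge_ok = row["dir_mirna"] == -row["dir_tf"]
        else:
            if row["tf_mirna_sign"] == ACTIVATION:
                category = "TF-activates-miRNA"
                edge_ok = row["dir_tf"] == row["dir_mirna"]
            else:
                category = "TF-represses-miRNA"
                edge_ok = row["dir_tf"] == -row["dir_mirna"]
        key = (row["mirna"], row["tf_or_gene1"], category)
        if key not in records:
            records[key] = {"edge_consistent": bool(edge_ok), "n_loops": 0}
        records[key]["n_loops"] += 1
    rows = [
        (
            mirna,
            tf,
            category,
            "consistent" if rec["edge_consistent"] else "inconsistent",
            rec["n_loops"],
        )
        for (mirna, tf, category), rec in sorted(records.items())
    ]
    return pd.DataFrame(
        rows, columns=["mirna", "tf", "interaction", "edge_consistency", "n_loops"]
    )


def query_loops(
    loops: pd.DataFrame,
    node_filters: dict | None = None,
    type_filters: dict | None = None,
    consistency_filter: str | None = None,
) -> pd.DataFrame:
    """Filter loops by node-id sets and/or type/subtype/coherence/consistency.

    ``node_filters`` maps any of {"mirna", "tf_or_gene1", "mrna_or_gene2"} to
    an id collection; ``type_filters`` maps any of {"loop_type", "subtype",
    "coherence"} to allowed values.  Empty filters return the input.
    """
    out = loops
    if node_filters:
        for col, ids in node_filters.items():
            if col not in ("mirna", "tf_or_gene1", "mrna_or_gene2"):
                raise SchemaError(f"unknown node role {col!r}")
            out = out[out[col].isin(set(ids))]
    if type_filters:
        for col, allowed in type_filters.items():
            if col not in ("loop_type", "subtype", "coherence", "group"):
                raise SchemaError(f"unknown type filter {col!r}")
            allowed = {allowed} if isinstance(allowed, str) else set(allowed)
            out = out[out[col].isin(allowed)]
    if consistency_filter is not None:
        out = out[out["consistent"] == consistency_filter]
    return out.copy()
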