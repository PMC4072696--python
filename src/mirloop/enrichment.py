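"""Rank-based gene-set enrichment rescuing regulators missed per-transcript.

Three set families are tested against the per-feature moderated t-statistics
of the mRNA data: TF target sets (built from the regulatory prior for TFs
not already called differentially expressed), validated-target sets for a
whitelist of miRNAs, and pathway membership sets.  Each set is compared to
its complement with a Wilcoxon rank-sum test; undirected ("mixed") tests
rank |t|, directed tests rank signed t.  BH adjustment is applied within
each family separately; miRNA sets are tested for enrichment in the
direction opposite to the miRNA's own deregulation, since a repressor's
targets are expected to shift against it.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust
from .types import EV_BOTH, EV_VALIDATED, GeneSet, PipelineConfig, PriorDB, SchemaError

logger = logging.getLogger(__name__)

EXACT_UNIVERSE_LIMIT = 10

ENRICHMENT_COLUMNS = ["set_id", "index_kind", "alternative", "p", "fdr", "implied_direction"]

COMBINED_COLUMNS = ["feature_id", "source", "direction", "mht_p", "mht_fdr", "gsea_fdr"]


def build_tf_sets(
    priordb: PriorDB,
    universe,
    de_results: pd.DataFrame,
    config: PipelineConfig,
) -> list:
    """One target set per measured, not-yet-significant TF with in-universe targets."""
    universe = set(universe)
    targets_by_tf = {}
    for e in priordb.tf_gene:
        targets_by_tf.setdefault(e.regulator_id, set()).add(e.target_id)
    sets = []
    for tf in sorted(targets_by_tf):
        if tf not in de_results.index:
            continue
        if de_results.loc[tf, "fdr"] <= config.fdr_de:
            continue  # already called differentially expressed
        members = targets_by_tf[tf] & universe
        if not members:
            continue
        sets.append(GeneSet(set_id=tf, index_kind="TF", members=frozenset(members)))
    return sets


def build_mirna_sets(
    priordb: PriorDB,
    whitelist,
    universe,
    mirna_de_results: pd.DataFrame,
    config: PipelineConfig,
) -> list:
    """Validated-target sets for whitelist miRNAs not already significant.

    Sets smaller than ``config.min_set_size`` are discarded to limit the bias
    of rank tests on tiny sets.
    """
    universe = set(universe)
    validated = {}
    for e in priordb.mirna_gene:
        if e.evidence in (EV_VALIDATED, EV_BOTH):
            validated.setdefault(e.regulator_id, set()).add(e.target_id)
    sets = []
    for mirna in sorted(set(whitelist)):
        if mirna not in mirna_de_results.index:
            continue
        if mirna_de_results.loc[mirna, "fdr"] <= config.fdr_de:
            continue
        members = validated.get(mirna, set()) & universe
        if len(members) < config.min_set_size:
            continue
        sets.append(
            GeneSet(set_id=mirna, index_kind="miRNA", members=frozenset(members))
        )
    return sets


def pathway_sets(pathway_graphs, universe) -> list:
    """Membership sets (nodes intersected with the expression universe)."""
    universe = set(universe)
    sets = []
    for g in sorted(pathway_graphs, key=lambda g: g.pathway_id):
        members = g.nodes & universe
        if members:
            sets.append(
                GeneSet(
                    set_id=g.pathway_id, index_kind="pathway", members=frozenset(members)
                )
            )
    return sets


def rank_sum_set_test(
    statistics: pd.Series, gene_set: GeneSet, alternative: str = "mixed"
) -> float:
    """Wilcoxon rank-sum P value of set members versus non-members.

    alternative="mixed" ranks |t| one-sided toward large values; "up"/"down"
    rank signed t one-sided toward +/-.  Exact enumeration is used for
    universes of at most 10 features without ties, otherwise the normal
    approximation with tie correction.
    """
    members = [f for f in statistics.index if f in gene_set.members]
    others = [f for f in statistics.index if f not in gene_set.members]
    skipped = len(gene_set.members) - len(members)
    if skipped:
        logger.debug("set %s: %d members outside the universe", gene_set.set_id, skipped)
    if not members:
        raise SchemaError(f"set {gene_set.set_id!r} has no members in the universe")
    if not others:
        raise SchemaError(f"set {gene_set.set_id!r} covers the whole universe")

    if alternative == "mixed":
        x = statistics.loc[members].abs().to_numpy()
        y = statistics.loc[others].abs().to_numpy()
        side = "greater"
    elif alternative == "up":
        x = statistics.loc[members].to_numpy()
        y = statistics.loc[others].to_numpy()
        side = "greater"
    elif alternative == "down":
        x = statistics.loc[members].to_numpy()
        y = statistics.loc[others].to_numpy()
        side = "less"
    else:
        raise SchemaError(f"unknown alternative {alternative!r}")

    n_total = len(x) + len(y)
    has_ties = len(np.unique(np.concatenate([x, y]))) < n_total
    if n_total <= EXACT_UNIVERSE_LIMIT and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=side, method=method)
    return float(res.pvalue)


def run_gsea(
    tf_sets,
    mirna_sets,
    path_sets,
    mrna_de: pd.DataFrame,
    mirna_de: pd.DataFrame,
    config: PipelineConfig,
) -> pd.DataFrame:
    """Test all three families and BH-adjust within each family separately."""
    statistics = mrna_de["t_mod"]
    frames = []
    for family, sets in (("TF", tf_sets), ("miRNA", mirna_sets), ("pathway", path_sets)):
        rows = []
        for gs in sets:
            if family == "miRNA":
                direction = int(mirna_de.loc[gs.set_id, "direction"])
                alternative = "down" if direction > 0 else "up"
            else:
                direction = 0
                alternative = "mixed"
            p = rank_sum_set_test(statistics, gs, alternative)
            rows.append((gs.set_id, family, alternative, p, direction))
        if not rows:
            continue
        fam = pd.DataFrame(
            rows, columns=["set_id", "index_kind", "alternative", "p", "implied_direction"]
        )
        fam["fdr"] = bh_adjust(fam["p"].to_numpy())
        frames.append(fam[ENRICHMENT_COLUMNS])
    if not frames:
        return pd.DataFrame(columns=ENRICHMENT_COLUMNS)
    return pd.concat(frames, ignore_index=True)


def significant_sets(enrichment: pd.DataFrame, family: str, config: PipelineConfig):
    sub = enrichment[
        (enrichment["index_kind"] == family) & (enrichment["fdr"] <= config.fdr_gsea)
    ]
    return list(sub["set_id"])


def combine_lists(
    mht_list: pd.DataFrame,
    gsea_results: pd.DataFrame,
    de_results: pd.DataFrame,
    family: str,
    config: PipelineConfig,
) -> pd.DataFrame:
    """Union of per-transcript calls and GSEA-rescued regulators.

    A feature significant by both routes is reported once with source MHT;
    the direction of a GSEA-sourced entry is the sign of its own moderated t.
    """
    rows = []
    for fid, rec in mht_list.iterrows():
        rows.append((fid, "MHT", int(rec["direction"]), rec["p"], rec["fdr"], np.nan))
    rescued = gsea_results[
        (gsea_results["index_kind"] == family)
        & (gsea_results["fdr"] <= config.fdr_gsea)
    ]
    mht_ids = set(mht_list.index)
    for _, rec in rescued.iterrows():
        fid = rec["set_id"]
        if fid in mht_ids or fid not in de_results.index:
            continue
        de = de_results.loc[fid]
        rows.append((fid, "GSEA", int(de["direction"]), de["p"], de["fdr"], rec["fdr"]))
    out = pd.DataFrame(rows, columns=COMBINED_COLUMNS)
    return out.sort_values("feature_id", kind="mergesort").reset_index(drop=True)
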