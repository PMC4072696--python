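from itertools import product

import numpy as np
import pandas as pd
import pytest

from mirloop import loops as lp
from mirloop.types import PathwayGraph, PriorDB, RegulatoryEdge, SchemaError


def tf_edge(tf, tgt, regulation="activation"):
    return RegulatoryEdge(tf, "TF", tgt, "gene", regulation)


def tm_edge(tf, mirna, regulation="activation"):
    return RegulatoryEdge(tf, "TF", mirna, "miRNA", regulation)


def mg_edge(mirna, gene, evidence="predicted"):
    return RegulatoryEdge(mirna, "miRNA", gene, "gene", "repression", evidence, 2)


def sign_product_oracle(loop_type, s1_token, s2_token=None):
    """Coherence from multiplying edge signs along the two regulator->mRNA paths."""
    s = {"activation": 1, "repression": -1}
    if loop_type == "I":
        direct = -1  # miRNA -| mRNA
        indirect = -1 * s[s1_token]  # miRNA -| TF, TF -> mRNA
    else:
        direct = s[s1_token]
        indirect = s[s2_token] * -1  # TF -> miRNA, miRNA -| mRNA
    return "coherent" if direct == indirect else "incoherent"


class TestClassifySubtype:
    def test_six_row_table(self):
        table = {
            ("I", "activation", None): ("none", "coherent"),
            ("I", "repression", None): ("none", "incoherent"),
            ("II", "activation", "repression"): ("A", "coherent"),
            ("II", "activation", "activation"): ("A", "incoherent"),
            ("II", "repression", "activation"): ("B", "coherent"),
            ("II", "repression", "repression"): ("B", "incoherent"),
        }
        for (lt, s1, s2), expected in table.items():
            assert lp.classify_subtype(lt, s1, s2) == expected

    def test_matches_sign_product_oracle_exhaustively(self):
        for s1 in ("activation", "repression"):
            _, coherence = lp.classify_subtype("I", s1)
            assert coherence == sign_product_oracle("I", s1)
            for s2 in ("activation", "repression"):
                subtype, coherence = lp.classify_subtype("II", s1, s2)
                assert coherence == sign_product_oracle("II", s1, s2)
                assert subtype == ("A" if s1 == "activation" else "B")

    def test_flipping_tf_mrna_sign_flips_coherence(self):
        flip = {"activation": "repression", "repression": "activation"}
        for s1 in flip:
            assert (
                lp.classify_subtype("I", s1)[1] != lp.classify_subtype("I", flip[s1])[1]
            )
            for s2 in flip:
                assert (
                    lp.classify_subtype("II", s1, s2)[1]
                    != lp.classify_subtype("II", flip[s1], s2)[1]
                )

    def test_invalid_tokens_rejected(self):
        with pytest.raises(SchemaError):
            lp.classify_subtype("I", "boost")
        with pytest.raises(SchemaError):
            lp.classify_subtype("II", "activation")  # missing TF->miRNA sign
        with pytest.raises(SchemaError):
            lp.classify_subtype("I", "activation", "repression")  # spurious edge


class TestRestrictPriors:
    def test_restriction_rules(self):
        db = PriorDB(
            tf_gene=[tf_edge("tfA", "g1"), tf_edge("tfX", "g1"), tf_edge("tfA", "far")],
            tf_mirna=[tm_edge("tfA", "m1"), tm_edge("tfA", "m9")],
            mirna_gene=[mg_edge("m1", "g1"), mg_edge("m9", "g1"), mg_edge("m1", "far")],
        )
        out = lp.restrict_priors(db, ["tfA"], ["m1"], ["tfA", "g1"])
        assert [(e.regulator_id, e.target_id) for e in out.tf_gene] == [("tfA", "g1")]
        assert [(e.regulator_id, e.target_id) for e in out.tf_mirna] == [("tfA", "m1")]
        assert [(e.regulator_id, e.target_id) for e in out.mirna_gene] == [("m1", "g1")]

    def test_empty_combined_lists_empty_everything(self):
        db = PriorDB(tf_gene=[tf_edge("tfA", "g1")], mirna_gene=[mg_edge("m1", "g1")])
        out = lp.restrict_priors(db, [], [], ["g1", "tfA"])
        assert not out.tf_gene and not out.tf_mirna and not out.mirna_gene


def brute_force_type1(tf_gene, mirna_gene):
    """O(n^3)-style join oracle over all (miRNA, TF->gene edge) combinations."""
    targeted = {(e.regulator_id, e.target_id) for e in mirna_gene}
    mirnas = {e.regulator_id for e in mirna_gene}
    found = set()
    for tg in tf_gene:
        for m in mirnas:
            if (m, tg.regulator_id) in targeted and (m, tg.target_id) in targeted:
                if tg.regulator_id != tg.target_id:
                    found.add((m, tg.regulator_id, tg.target_id, tg.regulation))
    return found


class TestBuildType1:
    def test_minimal_construction(self):
        out = lp.build_type1(
            [tf_edge("tfA", "g1", "activation")],
            [mg_edge("m", "tfA"), mg_edge("m", "g1")],
        )
        assert len(out) == 1
        row = out.iloc[0]
        assert (row["loop_type"], row["coherence"]) == ("I", "coherent")
        assert (row["mirna"], row["tf_or_gene1"], row["mrna_or_gene2"]) == ("m", "tfA", "g1")

    def test_mirna_must_target_both_nodes(self):
        out = lp.build_type1([tf_edge("tfA", "g1")], [mg_edge("m", "tfA")])
        assert out.empty

    def test_matches_brute_force_join_oracle(self):
        rng = np.random.default_rng(12)
        tfs = [f"tf{i}" for i in range(30)]
        genes = [f"g{i}" for i in range(200)]
        mirnas = [f"m{i}" for i in range(40)]
        tf_gene = []
        seen = set()
        for _ in range(150):
            tf, g = rng.choice(tfs), rng.choice(genes + tfs)
            if (tf, g) in seen or tf == g:
                continue
            seen.add((tf, g))
            tf_gene.append(tf_edge(tf, g, rng.choice(["activation", "repression"])))
        mirna_gene = []
        seen = set()
        for _ in range(600):
            m, g = rng.choice(mirnas), rng.choice(genes + tfs)
            if (m, g) in seen:
                continue
            seen.add((m, g))
            mirna_gene.append(mg_edge(m, g))
        out = lp.build_type1(tf_gene, mirna_gene)
        got = set(
            zip(out["mirna"], out["tf_or_gene1"], out["mrna_or_gene2"], out["tf_mrna_sign"])
        )
        assert got == brute_force_type1(tf_gene, mirna_gene)

    def test_order_invariant(self):
        tf_gene = [tf_edge("tfA", "g1"), tf_edge("tfB", "g2", "repression")]
        mirna_gene = [mg_edge("m", "tfA"), mg_edge("m", "g1"),
                      mg_edge("m", "tfB"), mg_edge("m", "g2")]
        a = lp.build_type1(tf_gene, mirna_gene)
        b = lp.build_type1(tf_gene[::-1], mirna_gene[::-1])
        pd.testing.assert_frame_equal(a, b)


class TestBuildType2:
    def test_activating_tf_with_repressed_target_is_iib_coherent(self):
        out = lp.build_type2(
            [tm_edge("tfA", "m", "activation")],
            [tf_edge("tfA", "g1", "repression")],
            [mg_edge("m", "g1")],
        )
        row = out.iloc[0]
        assert (row["subtype"], row["coherence"]) == ("B", "coherent")

    def test_double_repression_is_iib_incoherent(self):
        out = lp.build_type2(
            [tm_edge("tfA", "m", "repression")],
            [tf_edge("tfA", "g1", "repression")],
            [mg_edge("m", "g1")],
        )
        assert (out.iloc[0]["subtype"], out.iloc[0]["coherence"]) == ("B", "incoherent")

    def test_no_shared_targets_no_loops(self):
        out = lp.build_type2(
            [tm_edge("tfA", "m")], [tf_edge("tfA", "g1")], [mg_edge("m", "g2")]
        )
        assert out.empty


class TestBuildType3:
    def _graph(self, effect="direct"):
        return PathwayGraph("P1", {"g1", "g2"}, [("g1", "g2", effect)])

    def test_direct_edge_with_double_targeting(self):
        out = lp.build_type3(
            [self._graph()], [mg_edge("m", "g1"), mg_edge("m", "g2")],
            ["g1", "g2"], ["P1"],
        )
        assert len(out) == 1
        assert out.iloc[0]["pathway_id"] == "P1"

    def test_indirect_edge_excluded(self):
        out = lp.build_type3(
            [self._graph("indirect")], [mg_edge("m", "g1"), mg_edge("m", "g2")],
            ["g1", "g2"], ["P1"],
        )
        assert out.empty

    def test_single_target_excluded(self):
        out = lp.build_type3([self._graph()], [mg_edge("m", "g1")], ["g1", "g2"], ["P1"])
        assert out.empty

    def test_non_significant_pathway_excluded(self):
        out = lp.build_type3(
            [self._graph()], [mg_edge("m", "g1"), mg_edge("m", "g2")],
            ["g1", "g2"], [],
        )
        assert out.empty

    def test_unexpressed_endpoint_excluded(self):
        out = lp.build_type3(
            [self._graph()], [mg_edge("m", "g1"), mg_edge("m", "g2")], ["g1"], ["P1"]
        )
        assert out.empty


class TestLoopInvariants:
    def test_constructed_edges_exist_in_the_prior(self):
        rng = np.random.default_rng(3)
        tf_gene = [tf_edge(f"tf{i}", f"g{rng.integers(10)}") for i in range(8)]
        tf_gene = list({(e.regulator_id, e.target_id): e for e in tf_gene}.values())
        mirna_gene = [mg_edge(f"m{i % 4}", f"g{rng.integers(10)}") for i in range(20)]
        mirna_gene += [mg_edge(f"m{i % 4}", f"tf{rng.integers(8)}") for i in range(10)]
        mirna_gene = list({(e.regulator_id, e.target_id): e for e in mirna_gene}.values())
        pairs = {(e.regulator_id, e.target_id) for e in mirna_gene}
        tg_pairs = {(e.regulator_id, e.target_id) for e in tf_gene}
        out = lp.build_type1(tf_gene, mirna_gene)
        for _, row in out.iterrows():
            assert (row["tf_or_gene1"], row["mrna_or_gene2"]) in tg_pairs
            assert (row["mirna"], row["tf_or_gene1"]) in pairs
            assert (row["mirna"], row["mrna_or_gene2"]) in pairs
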