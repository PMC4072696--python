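from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mirloop import enrichment
from mirloop.types import (
    GeneSet,
    PipelineConfig,
    PriorDB,
    RegulatoryEdge,
    SchemaError,
)

from conftest import make_de_frame


def edge(reg, tgt, kind="TF", regulation="activation", evidence="predicted"):
    if kind == "miRNA":
        regulation = "repression"
    target_kind = "miRNA" if tgt.startswith("m") else "gene"
    return RegulatoryEdge(reg, kind, tgt, target_kind, regulation, evidence, 2)


class TestSetConstruction:
    def setup_method(self):
        self.config = PipelineConfig()
        self.universe = [f"g{i}" for i in range(20)]

    def test_tf_sets_skip_significant_and_unmeasured_tfs(self):
        db = PriorDB(tf_gene=[edge("g1", "g5"), edge("g1", "g6"),
                              edge("g2", "g7"), edge("g9", "zzz")])
        de = make_de_frame([1.0] * 20, self.universe,
                           fdr=[0.01] + [0.5] * 19)  # g0 not a TF; g1 has fdr 0.5
        de.loc["g1", "fdr"] = 0.5
        de.loc["g2", "fdr"] = 0.01  # already DE -> no set
        sets = enrichment.build_tf_sets(db, self.universe, de, self.config)
        assert [s.set_id for s in sets] == ["g1"]
        assert sets[0].members == frozenset({"g5", "g6"})  # zzz out of universe

    def test_mirna_sets_whitelist_and_size_rules(self):
        targets8 = [edge("m1", f"g{i}", "miRNA", evidence="validated") for i in range(8)]
        targets7 = [edge("m2", f"g{i}", "miRNA", evidence="validated") for i in range(7)]
        big_nonwhite = [edge("m3", f"g{i}", "miRNA", evidence="both") for i in range(12)]
        db = PriorDB(mirna_gene=targets8 + targets7 + big_nonwhite)
        de = make_de_frame([1.0, 1.0, 1.0], ["m1", "m2", "m3"], fdr=[0.9, 0.9, 0.9])
        sets = enrichment.build_mirna_sets(
            db, ["m1", "m2"], self.universe, de, self.config
        )
        assert [s.set_id for s in sets] == ["m1"]
        assert len(sets[0].members) == 8

    def test_sets_invariant_to_prior_row_order(self):
        edges = [edge("g1", "g5"), edge("g1", "g6"), edge("g1", "g7")]
        de = make_de_frame([1.0] * 20, self.universe, fdr=[0.5] * 20)
        a = enrichment.build_tf_sets(PriorDB(tf_gene=edges), self.universe, de, self.config)
        b = enrichment.build_tf_sets(
            PriorDB(tf_gene=edges[::-1]), self.universe, de, self.config
        )
        assert a == b


class TestRankSum:
    def test_exact_small_universe(self):
        stats_series = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        gs = GeneSet("S", "TF", frozenset({"c", "d"}))
        assert enrichment.rank_sum_set_test(stats_series, gs, "up") == pytest.approx(1 / 6)

    def test_exact_mirror_by_sign_flip(self):
        stats_series = pd.Series([-1.0, -2.0, 3.0, 4.0], index=list("abcd"))
        gs = GeneSet("S", "TF", frozenset({"a", "b"}))
        assert enrichment.rank_sum_set_test(stats_series, gs, "down") == pytest.approx(1 / 6)

    def test_exact_matches_enumeration_oracle(self):
        # oracle: enumerate all equally likely member-rank splits
        rng = np.random.default_rng(11)
        vals = rng.normal(size=9)
        s = pd.Series(vals, index=[f"f{i}" for i in range(9)])
        ranks = stats.rankdata(np.abs(vals))
        for k in (2, 4):
            gs = GeneSet("S", "TF", frozenset(s.index[:k]))
            observed = ranks[:k].sum()
            hits = sum(
                1
                for combo in combinations(range(9), k)
                if ranks[list(combo)].sum() >= observed - 1e-9
            )
            from math import comb
            p_oracle = hits / comb(9, k)
            p_impl = enrichment.rank_sum_set_test(s, gs, "mixed")
            assert p_impl == pytest.approx(p_oracle, abs=1e-12)

    def test_normal_approximation_close_to_exact(self):
        # universe of 12 takes the asymptotic path; compare with enumeration
        rng = np.random.default_rng(3)
        vals = rng.normal(size=12)
        s = pd.Series(vals, index=[f"f{i}" for i in range(12)])
        ranks = stats.rankdata(np.abs(vals))
        from math import comb
        for k in (3, 6):
            gs = GeneSet("S", "TF", frozenset(s.index[:k]))
            observed = ranks[:k].sum()
            hits = sum(
                1
                for combo in combinations(range(12), k)
                if ranks[list(combo)].sum() >= observed - 1e-9
            )
            p_oracle = hits / comb(12, k)
            p_impl = enrichment.rank_sum_set_test(s, gs, "mixed")
            assert abs(p_impl - p_oracle) < 0.02

    def test_null_p_values_approximately_uniform(self):
        rng = np.random.default_rng(9)
        vals = rng.normal(size=60)
        s = pd.Series(vals, index=[f"f{i}" for i in range(60)])
        ps = []
        for _ in range(1000):
            members = rng.choice(s.index, size=10, replace=False)
            gs = GeneSet("S", "TF", frozenset(members))
            ps.append(enrichment.rank_sum_set_test(s, gs, "mixed"))
        ks = stats.kstest(ps, "uniform").statistic
        assert ks < 0.05

    def test_set_equal_to_universe_refused(self):
        s = pd.Series([1.0, 2.0], index=["a", "b"])
        with pytest.raises(SchemaError, match="whole universe"):
            enrichment.rank_sum_set_test(s, GeneSet("S", "TF", frozenset("ab")), "mixed")


class TestRunGsea:
    def _null_de(self, seed, n=200):
        rng = np.random.default_rng(seed)
        t = rng.normal(size=n)
        return make_de_frame(t, [f"g{i}" for i in range(n)]), rng

    def test_planted_shifted_set_is_the_only_discovery(self):
        de, rng = self._null_de(5)
        members = rng.choice(de.index, 10, replace=False)
        idx = [list(de.index).index(g) for g in members]
        t = de["t_mod"].to_numpy()
        t[idx] += 2.0 * np.sign(t[idx])
        de["t_mod"] = t
        sets = [GeneSet("PLANTED", "TF", frozenset(members))] + [
            GeneSet(f"S{j}", "TF", frozenset(rng.choice(de.index, 10, replace=False)))
            for j in range(19)
        ]
        enr = enrichment.run_gsea(sets, [], [], de, de.iloc[:0], PipelineConfig())
        sig = enr[enr["fdr"] <= 0.25]["set_id"].tolist()
        assert sig == ["PLANTED"]

    def test_null_sets_calibrated(self):
        # under the global null BH discovers something with probability ~alpha,
        # so the zero-discovery rate should sit near 1 - 0.25
        zero = 0
        for seed in range(50):
            de, rng = self._null_de(seed + 500)
            sets = [
                GeneSet(f"S{j}", "TF", frozenset(rng.choice(de.index, 10, replace=False)))
                for j in range(20)
            ]
            enr = enrichment.run_gsea(sets, [], [], de, de.iloc[:0], PipelineConfig())
            zero += int((enr["fdr"] <= 0.25).sum() == 0)
        assert 0.6 <= zero / 50 <= 0.95

    def test_mirna_sets_tested_against_their_own_direction(self):
        de, rng = self._null_de(1)
        mirna_de = make_de_frame([2.0, -2.0], ["m_up", "m_down"])
        sets = [
            GeneSet("m_up", "miRNA", frozenset(de.index[:10])),
            GeneSet("m_down", "miRNA", frozenset(de.index[10:20])),
        ]
        enr = enrichment.run_gsea([], sets, [], de, mirna_de, PipelineConfig())
        alts = dict(zip(enr["set_id"], enr["alternative"]))
        assert alts == {"m_up": "down", "m_down": "up"}

    def test_bh_within_family_monotone_in_threshold(self):
        de, rng = self._null_de(2)
        sets = [
            GeneSet(f"S{j}", "TF", frozenset(rng.choice(de.index, 10, replace=False)))
            for j in range(15)
        ]
        enr = enrichment.run_gsea(sets, [], [], de, de.iloc[:0], PipelineConfig())
        counts = [int((enr["fdr"] <= thr).sum()) for thr in (0.5, 0.25, 0.1, 0.01)]
        assert counts == sorted(counts, reverse=True)


class TestCombineLists:
    def setup_method(self):
        self.config = PipelineConfig()

    def _gsea_frame(self, ids, fdr=0.1):
        return pd.DataFrame(
            {
                "set_id": ids,
                "index_kind": ["miRNA"] * len(ids),
                "alternative": ["down"] * len(ids),
                "p": [0.001] * len(ids),
                "fdr": [fdr] * len(ids),
                "implied_direction": [1] * len(ids),
            }
        )

    def test_feature_significant_by_both_routes_reported_once_as_mht(self):
        de = make_de_frame([2.0], ["m1"], p=[0.001], fdr=[0.01])
        combined = enrichment.combine_lists(
            de, self._gsea_frame(["m1"]), de, "miRNA", self.config
        )
        assert len(combined) == 1 and combined.loc[0, "source"] == "MHT"

    def test_disjoint_lists_union_sizes(self):
        ids = [f"m{i}" for i in range(23)]
        de = make_de_frame([1.0] * 23, ids, p=[0.001] * 23,
                           fdr=[0.01] * 18 + [0.9] * 5)
        mht = de[de["fdr"] <= 0.05]
        assert len(mht) == 18
        combined = enrichment.combine_lists(
            mht, self._gsea_frame(ids[18:]), de, "miRNA", self.config
        )
        assert len(combined) == 23
        assert (combined["source"] == "GSEA").sum() == 5

    def test_empty_gsea_returns_the_mht_list(self):
        de = make_de_frame([1.0, -1.0], ["m1", "m2"], fdr=[0.01, 0.02])
        combined = enrichment.combine_lists(
            de, self._gsea_frame([]), de, "miRNA", self.config
        )
        assert set(combined["feature_id"]) == {"m1", "m2"}
        assert (combined["source"] == "MHT").all()

    def test_gsea_entry_direction_is_its_own_t_sign(self):
        de = make_de_frame([1.0, -3.0], ["m1", "m2"], fdr=[0.01, 0.9])
        mht = de[de["fdr"] <= 0.05]
        combined = enrichment.combine_lists(
            mht, self._gsea_frame(["m2"]), de, "miRNA", self.config
        )
        rec = combined[combined["feature_id"] == "m2"].iloc[0]
        assert rec["direction"] == -1 and rec["source"] == "GSEA"
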