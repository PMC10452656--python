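import math

import numpy as np
import pandas as pd
import pytest

import epiburden as eb
from epiburden.enrichment import summarize_pathway_beta


def geneset_df(entries):
    return pd.DataFrame(
        [{"set_id": sid, "name": name, "genes": genes} for sid, name, genes in entries]
    )


def hypergeom_tail_enumeration(k, N, K, n):
    """P(X >= k) by direct summation of the hypergeometric pmf."""
    denom = math.comb(N, n)
    return sum(
        math.comb(K, j) * math.comb(N - K, n - j)
        for j in range(max(k, max(0, n - (N - K))), min(K, n) + 1)
    ) / denom


class TestSelectGenes:
    results = pd.DataFrame(
        {"gene": ["a", "b", "c"], "beta_group": [2.0, -1.0, 0.5], "q": [0.01, 0.04, 0.06]}
    )

    def test_threshold(self):
        sel = eb.select_genes(self.results, 0.05)
        assert list(sel["gene"]) == ["a", "b"]
        assert list(sel["beta_group"]) == [2.0, -1.0]

    def test_zero_threshold_empty(self):
        assert eb.select_genes(self.results, 0.0).empty

    def test_all_pass(self):
        sel = eb.select_genes(self.results, 1.0)
        assert len(sel) == 3


class TestORA:
    def test_worked_example(self):
        universe = [f"g{i}" for i in range(100)]
        selected = universe[:10]
        sets = geneset_df([("S1", "overlap five", universe[5:15])])
        out = eb.ora_hypergeometric(selected, universe, sets)
        assert out.iloc[0]["overlap"] == 5
        assert out.iloc[0]["p"] == pytest.approx(hypergeom_tail_enumeration(5, 100, 10, 10))

    def test_zero_overlap_is_one(self):
        universe = [f"g{i}" for i in range(20)]
        sets = geneset_df([("S1", "disjoint", universe[10:])])
        out = eb.ora_hypergeometric(universe[:5], universe, sets)
        assert out.iloc[0]["p"] == pytest.approx(1.0)

    def test_set_equal_to_universe_is_one(self):
        universe = [f"g{i}" for i in range(20)]
        sets = geneset_df([("S1", "everything", list(universe))])
        out = eb.ora_hypergeometric(universe[:7], universe, sets)
        assert out.iloc[0]["overlap"] == 7
        assert out.iloc[0]["p"] == pytest.approx(1.0)

    def test_selected_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="subset"):
            eb.ora_hypergeometric(["x"], ["a", "b"], geneset_df([("S1", "s", ["a"])]))

    def test_monotone_in_overlap(self):
        universe = [f"g{i}" for i in range(40)]
        prev = 1.1
        for k in range(0, 11):
            sets = geneset_df([("S", "s", universe[10 - k : 20 - k])])  # overlap k with first 10
            p = eb.ora_hypergeometric(universe[:10], universe, sets).iloc[0]["p"]
            assert p <= prev + 1e-12
            prev = p


class TestIteration:
    universe = [f"g{i}" for i in range(50)]

    def selected(self):
        return pd.DataFrame(
            {"gene": self.universe[:8], "beta_group": [1, 2, 3, -1, 2, 2, 4, -2.0]}
        )

    def test_degenerate_single_iteration(self):
        sets = geneset_df([("S1", "a", self.universe[:10]), ("S2", "b", self.universe[30:40])])
        out = eb.iterate_enrichment(self.selected(), self.universe, sets, n_iter=1,
                                    subsample_fraction=1.0, seed=1)
        single = eb.ora_hypergeometric(self.selected()["gene"].tolist(), self.universe, sets)
        for sid in ("S1", "S2"):
            row = out[out["set_id"] == sid].iloc[0]
            ref = single[single["set_id"] == sid].iloc[0]["p_adjusted"]
            assert row["lowest_p"] == pytest.approx(ref)
            assert row["highest_p"] == pytest.approx(ref)
            assert row["occurrence"] in (0.0, 1.0)

    def test_complete_overlap_always_occurs(self):
        sets = geneset_df([("S1", "contains all", self.universe[:8])])
        out = eb.iterate_enrichment(self.selected(), self.universe, sets, n_iter=50, seed=2)
        assert out.iloc[0]["occurrence"] == 1.0

    def test_seed_determinism(self):
        sets = geneset_df([("S1", "a", self.universe[:10])])
        a = eb.iterate_enrichment(self.selected(), self.universe, sets, n_iter=20, seed=3)
        b = eb.iterate_enrichment(self.selected(), self.universe, sets, n_iter=20, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_direction_split_gene_lists(self):
        sets = geneset_df([("S1", "a", self.universe[:8])])
        out = eb.iterate_enrichment(self.selected(), self.universe, sets, n_iter=5, seed=4)
        assert out.iloc[0]["genes_increased"] == "g0;g1;g2;g4;g5;g6"
        assert out.iloc[0]["genes_decreased"] == "g3;g7"

    def test_invalid_fraction(self):
        sets = geneset_df([("S1", "a", self.universe[:5])])
        with pytest.raises(ValueError):
            eb.iterate_enrichment(self.selected(), self.universe, sets, subsample_fraction=0.0)


class TestOccurrenceFilterAndIntersection:
    def table(self, ids, occ=1.0):
        return pd.DataFrame(
            {
                "set_id": ids,
                "name": [f"n{x}" for x in ids],
                "pathway_beta": 1.0,
                "genes_increased": "a;b",
                "genes_decreased": "",
                "lowest_p": 0.01,
                "highest_p": 0.02,
                "occurrence": occ,
            }
        )

    @pytest.mark.parametrize("occ, kept", [(0.9, True), (0.89, False)])
    def test_occurrence_boundary(self, occ, kept):
        out = eb.filter_by_occurrence(self.table(["S1"], occ), 0.9)
        assert (len(out) == 1) is kept

    def test_zero_threshold_identity(self):
        t = self.table(["S1", "S2"], 0.1)
        assert len(eb.filter_by_occurrence(t, 0.0)) == 2

    def test_shared_single_id(self):
        tables = [self.table(x) for x in (["R1", "A"], ["R1", "B"], ["R1", "C"])]
        out = eb.intersect_pathways(tables)
        assert out["set_id"].tolist() == ["R1"]

    def test_disjoint_empty(self):
        out = eb.intersect_pathways([self.table(["A"]), self.table(["B"])])
        assert out.empty

    def test_order_invariant(self):
        tables = [self.table(["X", "Y"]), self.table(["Y", "Z"]), self.table(["Y"])]
        a = eb.intersect_pathways(tables, ["d1", "d2", "d3"])
        b = eb.intersect_pathways(tables[::-1], ["d3", "d2", "d1"])
        assert a["set_id"].tolist() == b["set_id"].tolist() == ["Y"]

    def test_self_intersection_identity(self):
        t = self.table(["A", "B", "C"])
        out = eb.intersect_pathways([t, t.copy()])
        assert out["set_id"].tolist() == ["A", "B", "C"]

    def test_requires_two_tables(self):
        with pytest.raises(ValueError):
            eb.intersect_pathways([self.table(["A"])])


class TestPathwayBeta:
    def row(self, inc, dec):
        return pd.Series({"genes_increased": inc, "genes_decreased": dec})

    def test_mean_of_members(self):
        assert summarize_pathway_beta(self.row("a;b", ""), {"a": 2, "b": 4}) == 3

    def test_single_member(self):
        assert summarize_pathway_beta(self.row("a", ""), {"a": 7.5}) == 7.5

    def test_sign_mixed(self):
        assert summarize_pathway_beta(self.row("b", "a"), {"a": -1, "b": 3}) == 1

    def test_no_members_flagged(self):
        assert np.isnan(summarize_pathway_beta(self.row("", ""), {}))


class TestGMTRoundTrip:
    def test_write_read(self, tmp_path):
        sets = geneset_df([("S1", "first pathway", ["a", "b", "c"]), ("S2", "second", ["d", "e"])])
        path = tmp_path / "sets.gmt"
        eb.write_gmt(sets, path)
        again = eb.read_gmt(path)
        pd.testing.assert_frame_equal(sets, again)
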