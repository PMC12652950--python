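"""Ranking, GSEA running sums, hypergeometric ORA, kappa grouping."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rewirenet import (
    GeneSetCollection,
    cohen_kappa,
    gsea_preranked,
    kappa_group_terms,
    ora_hypergeometric,
    rank_genes,
)
from rewirenet.enrichment import enrichment_score, enrichment_score_reference


class TestRankGenes:
    def test_printed_formula_cases(self):
        de = pd.DataFrame(
            {"log2fc": [-2.0, 0.0, 1.0], "p": [0.01, 0.5, 0.001]},
            index=["a", "b", "c"],
        )
        ranked = rank_genes(de).set_index("gene")["score"]
        assert ranked["a"] == pytest.approx(-2.0)
        assert ranked["b"] == 0.0
        assert ranked["c"] == pytest.approx(3.0)

    def test_order_is_descending_and_deterministic(self):
        de = pd.DataFrame(
            {"log2fc": [1.0, 2.0, -1.0, 1.0], "p": [0.1, 0.1, 0.01, 0.1]},
            index=["b", "a", "d", "c"],
        )
        ranked = rank_genes(de)
        assert list(ranked["gene"]) == ["a", "b", "c", "d"]

    def test_zero_p_is_clamped(self):
        de = pd.DataFrame({"log2fc": [1.0], "p": [0.0]}, index=["a"])
        score = rank_genes(de)["score"].iloc[0]
        assert np.isfinite(score) and score == pytest.approx(300.0)


class TestEnrichmentScore:
    def test_single_top_gene_unweighted(self):
        scores = np.array([4.0, 2.0, 1.0, -3.0])
        es, leading = enrichment_score(scores, np.array([0]), weight=0.0)
        assert es == pytest.approx(1.0)
        assert leading == 1

    def test_matches_reference_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = rng.integers(8, 40)
            scores = np.sort(rng.normal(size=n))[::-1]
            k = rng.integers(1, n - 1)
            hits = rng.choice(n, size=k, replace=False)
            mask = np.zeros(n, dtype=bool)
            mask[hits] = True
            for weight in (0.0, 1.0):
                es, _ = enrichment_score(scores, hits, weight)
                ref = enrichment_score_reference(scores, mask, weight)
                assert es == pytest.approx(ref, abs=1e-12)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        data=st.data(),
        n=st.integers(min_value=5, max_value=25),
    )
    def test_reference_equivalence_property(self, data, n):
        scores = np.linspace(3.0, -3.0, n)
        k = data.draw(st.integers(min_value=1, max_value=n - 1))
        hits = np.array(
            data.draw(
                st.lists(
                    st.integers(min_value=0, max_value=n - 1),
                    min_size=k,
                    max_size=k,
                    unique=True,
                )
            )
        )
        mask = np.zeros(n, dtype=bool)
        mask[hits] = True
        es, _ = enrichment_score(scores, hits, weight=1.0)
        assert es == pytest.approx(
            enrichment_score_reference(scores, mask, 1.0), abs=1e-12
        )

    def test_reversing_the_list_negates_es_at_weight_zero(self):
        rng = np.random.default_rng(1)
        scores = np.sort(rng.normal(size=30))[::-1]
        hits = rng.choice(30, size=6, replace=False)
        es, _ = enrichment_score(scores, hits, weight=0.0)
        rev_hits = 30 - 1 - hits
        es_rev, _ = enrichment_score(scores[::-1].copy(), rev_hits, weight=0.0)
        assert es_rev == pytest.approx(-es, abs=1e-12)


class TestGseaPreranked:
    def _ranked(self, n=40, seed=0):
        rng = np.random.default_rng(seed)
        de = pd.DataFrame(
            {"log2fc": rng.normal(size=n), "p": rng.uniform(0.001, 1, size=n)},
            index=[f"g{i:02d}" for i in range(n)],
        )
        return rank_genes(de)

    def test_permutation_p_respects_floor_and_determinism(self):
        ranked = self._ranked()
        top = ranked["gene"].head(6).tolist()
        coll = GeneSetCollection(sets={"top": top})
        a = gsea_preranked(ranked, coll, n_perm=200, seed=5)
        b = gsea_preranked(ranked, coll, n_perm=200, seed=5)
        assert a.equals(b)
        assert a["p"].iloc[0] >= 1 / 201
        assert a["nes"].iloc[0] > 0 and a["es"].iloc[0] > 0

    def test_whole_universe_set_is_skipped(self):
        ranked = self._ranked(n=20)
        coll = GeneSetCollection(sets={"all": ranked["gene"].tolist()})
        out = gsea_preranked(ranked, coll, min_size=1, max_size=500)
        assert len(out) == 0

    def test_no_overlap_set_is_skipped(self):
        ranked = self._ranked(n=20)
        coll = GeneSetCollection(sets={"alien": ["zz1", "zz2", "zz3", "zz4", "zz5"]})
        assert len(gsea_preranked(ranked, coll)) == 0


class TestOra:
    def test_full_overlap_worked_example(self):
        # N=10, K=5, n=5, overlap=5 -> 1 / C(10,5)
        universe = [f"g{i}" for i in range(10)]
        coll = GeneSetCollection(sets={"s": universe[:5]})
        out = ora_hypergeometric(universe[:5], coll, universe)
        assert out["p"].iloc[0] == pytest.approx(1 / math.comb(10, 5))
        assert out["fold_enrichment"].iloc[0] == pytest.approx(2.0)

    def test_disjoint_query(self):
        universe = [f"g{i}" for i in range(10)]
        coll = GeneSetCollection(sets={"s": universe[:4]})
        out = ora_hypergeometric(universe[6:], coll, universe)
        assert out["fold_enrichment"].iloc[0] == 0.0
        assert out["p"].iloc[0] == pytest.approx(1.0)

    def test_empty_query_raises(self):
        coll = GeneSetCollection(sets={"s": ["g1"]})
        with pytest.raises(ValueError):
            ora_hypergeometric(["outside"], coll, ["g1", "g2"])

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        n_uni=st.integers(min_value=4, max_value=20),
        data=st.data(),
    )
    def test_exact_against_combinatorial_enumeration(self, n_uni, data):
        k_set = data.draw(st.integers(min_value=1, max_value=n_uni))
        n_query = data.draw(st.integers(min_value=1, max_value=n_uni))
        overlap_max = min(k_set, n_query)
        overlap_min = max(0, k_set + n_query - n_uni)
        overlap = data.draw(
            st.integers(min_value=overlap_min, max_value=overlap_max)
        )
        universe = [f"g{i}" for i in range(n_uni)]
        members = universe[:k_set]
        query = universe[:overlap] + universe[k_set : k_set + (n_query - overlap)]
        out = ora_hypergeometric(query, GeneSetCollection(sets={"s": members}), universe)
        expected = sum(
            math.comb(k_set, i) * math.comb(n_uni - k_set, n_query - i)
            for i in range(overlap, overlap_max + 1)
        ) / math.comb(n_uni, n_query)
        assert out["p"].iloc[0] == pytest.approx(expected, rel=1e-9)


class TestKappaGrouping:
    def test_agreement_table_worked_example(self):
        # a=30, b=10, c=10, d=50 over N=100 -> kappa = 0.28 / 0.48
        v1 = np.zeros(100, dtype=bool)
        v2 = np.zeros(100, dtype=bool)
        v1[:40] = True
        v2[:30] = True
        v2[40:50] = True
        assert cohen_kappa(v1, v2) == pytest.approx(0.28 / 0.48)

    def test_identical_sets_share_a_group(self):
        universe = [f"g{i}" for i in range(30)]
        coll = GeneSetCollection(sets={"t1": universe[:8], "t2": universe[:8]})
        result = pd.DataFrame({"set": ["t1", "t2"], "p": [0.01, 0.02]})
        groups = kappa_group_terms(result, coll, universe)
        assert groups["group"].nunique() == 1
        assert set(groups["representative"]) == {"t1"}
        assert groups["group_p"].iloc[0] == 0.01

    def test_disjoint_sets_stay_separate(self):
        universe = [f"g{i}" for i in range(40)]
        coll = GeneSetCollection(sets={"t1": universe[:5], "t2": universe[5:10]})
        result = pd.DataFrame({"set": ["t1", "t2"], "p": [0.01, 0.02]})
        groups = kappa_group_terms(result, coll, universe)
        assert groups["group"].nunique() == 2

    def test_grouping_ignores_input_order(self):
        universe = [f"g{i}" for i in range(50)]
        coll = GeneSetCollection(
            sets={
                "t1": universe[:10],
                "t2": universe[2:12],
                "t3": universe[30:40],
            }
        )
        result = pd.DataFrame(
            {"set": ["t1", "t2", "t3"], "p": [0.03, 0.01, 0.002]}
        )
        fwd = kappa_group_terms(result, coll, universe)
        rev = kappa_group_terms(result.iloc[::-1], coll, universe)
        assert fwd.equals(rev)


class TestGmtRoundTrip:
    def test_read_write(self, tmp_path):
        coll = GeneSetCollection(
            sets={"s1": ["a", "b"], "s2": ["c"]},
            descriptions={"s1": "first", "s2": "second"},
        )
        path = tmp_path / "x.gmt"
        coll.write_gmt(path)
        back = GeneSetCollection.read_gmt(path)
        assert back.sets == coll.sets
        assert back.descriptions == coll.descriptions
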