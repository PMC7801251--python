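import numpy as np
import pytest
from scipy import stats

from dctnet import (
    AnchorSet,
    composite_rank,
    consensus_candidates,
    pcc,
    rank_tissue,
    relatedness_score,
)
from dctnet.ranking import GeneRanking


class TestAnchorSet:
    def test_dedup(self):
        assert AnchorSet(["a", "b", "a"]).gene_ids == ["a", "b"]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            AnchorSet([])


class TestRelatednessScore:
    def test_mean_of_anchor_correlations(self):
        rng = np.random.default_rng(1)
        H = rng.uniform(0, 5, (7, 3))
        genes = ["u", "v1", "v2"]
        expected = (pcc(H[:, 0], H[:, 1]) + pcc(H[:, 0], H[:, 2])) / 2.0
        score = relatedness_score("u", AnchorSet(["v1", "v2"]), H, genes)
        assert score == pytest.approx(expected, abs=1e-12)

    def test_perfectly_correlated_gene_scores_one(self):
        base = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        H = np.column_stack([base, 2 * base, base + 1.0])
        score = relatedness_score("u", AnchorSet(["v1", "v2"]),
                                  H, ["u", "v1", "v2"])
        assert score == pytest.approx(1.0)

    def test_brute_force_oracle(self):
        # direct-summation oracle: loop over scalar PCCs and average
        rng = np.random.default_rng(7)
        n_genes, n_anchors = 30, 5
        H = rng.uniform(0, 5, (7, n_genes + n_anchors))
        genes = [f"g{i}" for i in range(n_genes)]
        anchors = [f"a{i}" for i in range(n_anchors)]
        ids = genes + anchors
        aset = AnchorSet(anchors)
        for i, g in enumerate(genes):
            oracle = np.mean([pcc(H[:, i], H[:, n_genes + j])
                              for j in range(n_anchors)])
            assert relatedness_score(g, aset, H, ids) == pytest.approx(
                oracle, abs=1e-12)

    def test_duplicate_anchor_leaves_score_unchanged(self):
        rng = np.random.default_rng(3)
        H = rng.uniform(0, 5, (7, 3))
        ids = ["u", "v1", "v2"]
        a = relatedness_score("u", AnchorSet(["v1", "v2"]), H, ids)
        b = relatedness_score("u", AnchorSet(["v1", "v2", "v1"]), H, ids)
        assert a == b

    def test_constant_anchor_skipped_with_warning(self):
        rng = np.random.default_rng(9)
        H = rng.uniform(0, 5, (7, 3))
        H[:, 2] = 4.2
        ids = ["u", "v1", "v2"]
        with pytest.warns(UserWarning):
            score = relatedness_score("u", AnchorSet(["v1", "v2"]), H, ids)
        assert score == pytest.approx(pcc(H[:, 0], H[:, 1]), abs=1e-12)

    def test_score_bounded(self):
        rng = np.random.default_rng(21)
        H = rng.uniform(0, 5, (7, 6))
        ids = [f"g{i}" for i in range(6)]
        s = relatedness_score("g0", AnchorSet(ids[1:]), H, ids)
        assert abs(s) <= 1.0


class TestRankTissue:
    def _setup(self, scores_by_gene):
        """Build H whose columns give predictable anchor correlations."""
        rng = np.random.default_rng(0)
        anchor = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0])
        cols, ids = [anchor], ["anchor"]
        for g, rho in scores_by_gene.items():
            noise = rng.normal(0, 1, 7)
            noise -= np.polyval(np.polyfit(anchor, noise, 1), anchor)
            col = rho * (anchor - anchor.mean()) / anchor.std() + \
                np.sqrt(max(1 - rho**2, 0)) * noise / max(noise.std(), 1e-9)
            cols.append(col + 10.0)
            ids.append(g)
        return np.column_stack(cols), ids

    def test_top_list_sorted(self):
        H, ids = self._setup({"g1": 0.9, "g2": 0.1, "g3": 0.5})
        r = rank_tissue(H, ids, {"g1", "g2", "g3"}, AnchorSet(["anchor"]),
                        top_n=2)
        assert r.top_list == ["g1", "g3"]

    def test_ties_lexicographic(self):
        base = np.array([1.0, 5.0, 2.0, 4.0, 3.0])
        H = np.column_stack([base, 2 * base, base * 3, base + 1])
        ids = ["anchor", "gb", "ga", "gc"]
        r = rank_tissue(H, ids, {"ga", "gb", "gc"}, AnchorSet(["anchor"]),
                        top_n=3)
        assert r.top_list == ["ga", "gb", "gc"]

    def test_anchors_excluded_from_candidates(self):
        rng = np.random.default_rng(2)
        H = rng.uniform(0, 5, (7, 4))
        ids = ["a1", "g1", "g2", "g3"]
        r = rank_tissue(H, ids, set(ids), AnchorSet(["a1"]), top_n=3)
        assert "a1" not in r.scores

    def test_small_gene_set_warns(self):
        rng = np.random.default_rng(4)
        H = rng.uniform(0, 5, (7, 3))
        ids = ["a1", "g1", "g2"]
        with pytest.warns(UserWarning):
            r = rank_tissue(H, ids, set(ids), AnchorSet(["a1"]), top_n=30)
        assert len(r.top_list) == 2


class TestConsensus:
    def _ranking(self, tissue, genes):
        return GeneRanking(tissue_id=tissue,
                           scores={g: 1.0 - i * 0.1
                                   for i, g in enumerate(genes)},
                           top_list=list(genes))

    def test_min_tissue_threshold(self):
        rankings = [self._ranking(f"t{i}", ["keep", f"only{i}"])
                    for i in range(5)]
        cc = consensus_candidates(rankings, min_tissues=4)
        assert cc.candidates == ["keep"]
        assert cc.tissue_counts["keep"] == 5

    def test_min_tissues_one_is_union(self):
        rankings = [self._ranking("t1", ["a", "b"]),
                    self._ranking("t2", ["b", "c"])]
        cc = consensus_candidates(rankings, min_tissues=1)
        assert set(cc.candidates) == {"a", "b", "c"}

    def test_monotone_in_min_tissues(self):
        rng = np.random.default_rng(11)
        pool = [f"g{i}" for i in range(12)]
        rankings = [self._ranking(f"t{i}",
                                  list(rng.choice(pool, 6, replace=False)))
                    for i in range(7)]
        prev = None
        for mt in (1, 2, 3, 4, 5):
            cur = set(consensus_candidates(rankings, mt).candidates)
            if prev is not None:
                assert cur <= prev
            prev = cur

    def test_empty_rankings_rejected(self):
        with pytest.raises(ValueError):
            consensus_candidates([], 4)


class TestCompositeRank:
    def test_best_everywhere_gets_product_one(self):
        scores = {"a": 0.9, "b": 0.5}
        fc = {"a": 3.0, "b": 2.0}
        deg = {"a": 10, "b": 1}
        out = composite_rank(scores, fc, deg)
        assert out["a"] == 1.0
        assert out["b"] == 8.0

    def test_five_gene_hand_oracle(self):
        genes = list("abcde")
        scores = dict(zip(genes, [0.9, 0.8, 0.7, 0.6, 0.5]))  # ranks 1..5
        fc = dict(zip(genes, [1.0, 2.0, 3.0, 4.0, 5.0]))      # ranks 5..1
        deg = dict(zip(genes, [5, 3, 4, 1, 2]))               # 1,4,2? no:
        # degree ranks (desc): a=1, c=2, b=3, e=4, d=5
        out = composite_rank(scores, fc, deg)
        assert out == {"a": 1 * 5 * 1, "b": 2 * 4 * 3, "c": 3 * 3 * 2,
                       "d": 4 * 2 * 5, "e": 5 * 1 * 4}

    def test_rank_ties_share_best_position(self):
        out = composite_rank({"a": 0.5, "b": 0.5}, {"a": 2.0, "b": 2.0},
                             {"a": 1, "b": 1})
        assert out["a"] == out["b"] == 1.0

    def test_missing_gene_names_map(self):
        with pytest.raises(KeyError, match="fc"):
            composite_rank({"a": 1.0}, {}, {"a": 1})

    def test_matches_rankdata_oracle(self):
        rng = np.random.default_rng(23)
        genes = [f"g{i}" for i in range(15)]
        scores = dict(zip(genes, rng.normal(size=15)))
        fc = dict(zip(genes, rng.uniform(1, 5, 15)))
        deg = dict(zip(genes, rng.integers(0, 10, 15)))
        out = composite_rank(scores, fc, deg)
        expected = (stats.rankdata([-scores[g] for g in genes], method="min")
                    * stats.rankdata([-fc[g] for g in genes], method="min")
                    * stats.rankdata([-deg[g] for g in genes], method="min"))
        for g, e in zip(genes, expected):
            assert out[g] == e
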