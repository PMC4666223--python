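"""Gene set enrichment: running sum, permutation null, leading edge."""

import numpy as np
import pytest

from dmrank.gsea import (
    RankedGeneList,
    EnrichmentResult,
    enrichment_score,
    leading_edge,
    leading_edge_overlap,
    permutation_p,
    rank_genes,
)
from dmrank.io import Region
from dmrank.region_stats import RegionResult


def es_oracle(genes, scores, members, weight_p):
    """Independent running-sum evaluation, written directly from the
    weighted Kolmogorov–Smirnov definition."""
    members = set(members)
    hits = [g in members for g in genes]
    n_hit = sum(hits)
    n_miss = len(genes) - n_hit
    denom = sum(abs(s) ** weight_p for g, s in zip(genes, scores) if g in members)
    running, best, best_i = 0.0, 0.0, 0
    for i, (g, s) in enumerate(zip(genes, scores)):
        if g in members:
            running += (abs(s) ** weight_p) / denom if denom > 0 else 1.0 / n_hit
        else:
            running -= 1.0 / n_miss
        if abs(running) > abs(best):
            best, best_i = running, i
    return best, best_i + 1


def region_result(name, gene, q, change, chrom="chr1", start=None):
    start = start if start is not None else hash(name) % 10_000
    return RegionResult(
        region=Region(chrom, start, start + 100, name, gene),
        group_pair=("A", "B"),
        probe_ids=[],
        n_probes=3,
        p_a=q, p_b=q, q_a=q, q_b=q,
        direction="B" if change >= 0 else "A",
        q=q,
        change_min=change, change_median=change, change_max=change,
    )


def random_ranked(rng, n=50):
    genes = [f"G{i}" for i in range(n)]
    scores = np.sort(rng.normal(size=n))[::-1]
    return RankedGeneList(genes=genes, score=scores)


class TestRankGenes:
    def test_best_region_per_gene(self):
        results = [
            region_result("r1", "GENE1", 0.01, 0.2),
            region_result("r2", "GENE1", 0.2, 0.5),
        ]
        ranked = rank_genes(results)
        assert ranked.genes == ["GENE1"]
        assert ranked.score[0] == pytest.approx(-np.log10(0.01))

    def test_positive_change_ranks_first_on_equal_q(self):
        results = [
            region_result("r1", "UP", 0.05, +0.3),
            region_result("r2", "DOWN", 0.05, -0.3),
        ]
        ranked = rank_genes(results)
        assert ranked.genes == ["UP", "DOWN"]
        assert ranked.score[0] > 0 > ranked.score[1]

    def test_five_region_expected_order(self):
        # hand-evaluated: score = sign(change) * -log10(q)
        results = [
            region_result("r1", "A1", 0.001, +0.1),  # +3
            region_result("r2", "B2", 0.01, +0.2),  # +2
            region_result("r3", "C3", 0.5, +0.1),  # +0.301
            region_result("r4", "D4", 0.1, -0.2),  # -1
            region_result("r5", "E5", 0.001, -0.3),  # -3
        ]
        ranked = rank_genes(results)
        assert ranked.genes == ["A1", "B2", "C3", "D4", "E5"]

    def test_no_gene_links_rejected(self):
        with pytest.raises(ValueError):
            rank_genes([region_result("r1", None, 0.01, 0.1)])


class TestEnrichmentScore:
    def test_single_top_hit_unweighted(self):
        ranked = RankedGeneList(
            genes=[f"G{i}" for i in range(10)],
            score=np.linspace(5, -5, 10),
        )
        es, peak = enrichment_score(ranked, {"G0"}, weight_p=0)
        assert es == pytest.approx(1.0)
        assert peak == 1

    def test_empty_intersection_untestable(self):
        ranked = RankedGeneList(genes=["A", "B"], score=np.array([1.0, -1.0]))
        assert enrichment_score(ranked, {"ZZZ"}) is None

    @pytest.mark.parametrize("weight_p", [0.0, 1.0, 2.0])
    def test_matches_independent_oracle(self, weight_p):
        rng = np.random.default_rng(314)
        for _ in range(30):
            ranked = random_ranked(rng)
            k = rng.integers(2, 12)
            members = rng.choice(ranked.genes, size=k, replace=False)
            es, peak = enrichment_score(ranked, members, weight_p)
            es_ref, peak_ref = es_oracle(ranked.genes, ranked.score, members, weight_p)
            assert es == pytest.approx(es_ref, abs=1e-12)
            assert peak == peak_ref

    def test_unweighted_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(7)
        ranked = random_ranked(rng)
        members = set(rng.choice(ranked.genes, size=8, replace=False))
        es1, p1 = enrichment_score(ranked, members, weight_p=0)
        transformed = RankedGeneList(
            genes=ranked.genes, score=np.exp(ranked.score / 3)
        )
        es2, p2 = enrichment_score(transformed, members, weight_p=0)
        assert es1 == pytest.approx(es2, abs=1e-12) and p1 == p2

    def test_reversal_negates_unweighted_es(self):
        rng = np.random.default_rng(8)
        ranked = random_ranked(rng)
        members = set(rng.choice(ranked.genes, size=6, replace=False))
        es_fwd, _ = enrichment_score(ranked, members, weight_p=0)
        rev = RankedGeneList(genes=ranked.genes[::-1], score=ranked.score[::-1] * -1)
        es_rev, _ = enrichment_score(rev, members, weight_p=0)
        assert abs(es_fwd) == pytest.approx(abs(es_rev), abs=1e-9)
        assert np.sign(es_fwd) == -np.sign(es_rev)


class TestPermutationP:
    def test_seed_determinism(self):
        rng = np.random.default_rng(10)
        ranked = random_ranked(rng)
        members = list(rng.choice(ranked.genes, size=6, replace=False))
        p1 = permutation_p(ranked, members, n_perm=200, seed=5)
        p2 = permutation_p(ranked, members, n_perm=200, seed=5)
        assert p1 == p2

    def test_lower_bound_when_es_dominates(self):
        # a set that is exactly the top genes: no random subset beats it
        ranked = RankedGeneList(
            genes=[f"G{i}" for i in range(40)],
            score=np.linspace(10, -10, 40),
        )
        p = permutation_p(ranked, {"G0", "G1", "G2"}, n_perm=200, seed=1)
        assert p == pytest.approx(1 / 201)

    def test_two_seeds_agree_within_binomial_error(self):
        rng = np.random.default_rng(12)
        ranked = random_ranked(rng, n=60)
        members = list(ranked.genes[5:13])  # moderate signal near the top
        p1 = permutation_p(ranked, members, n_perm=2000, seed=100)
        p2 = permutation_p(ranked, members, n_perm=2000, seed=200)
        se = np.sqrt(max(p1, 1 / 2001) * (1 - p1) / 2000)
        assert abs(p1 - p2) <= 3 * se + 1e-12

    def test_null_p_approximately_uniform(self):
        rng = np.random.default_rng(77)
        ranked = random_ranked(rng, n=80)
        from scipy.stats import kstest

        ps = []
        for i in range(200):
            members = rng.choice(ranked.genes, size=8, replace=False)
            ps.append(permutation_p(ranked, members, n_perm=199, seed=1000 + i))
        assert kstest(ps, "uniform").statistic < 0.1

    def test_small_n_perm_rejected(self):
        ranked = RankedGeneList(genes=["A", "B"], score=np.array([1.0, -1.0]))
        with pytest.raises(ValueError):
            permutation_p(ranked, {"A"}, n_perm=10)


class TestLeadingEdge:
    def test_positive_es_takes_ranks_up_to_peak(self):
        ranked = RankedGeneList(
            genes=["A", "B", "C", "D"], score=np.array([3.0, 2.0, -1.0, -2.0])
        )
        assert leading_edge(ranked, {"A", "D"}, es=0.5, peak_index=2) == ["A"]

    def test_negative_es_takes_ranks_after_peak(self):
        ranked = RankedGeneList(
            genes=["A", "B", "C", "D"], score=np.array([3.0, 2.0, -1.0, -2.0])
        )
        assert leading_edge(ranked, {"A", "D"}, es=-0.5, peak_index=2) == ["D"]

    @pytest.mark.parametrize(
        "edge_a,edge_b,expected",
        [
            (["A", "B", "C"], ["A", "B", "C"], 1.0),
            (["A", "B"], ["C", "D"], 0.0),
            (["A", "B", "C"], ["B", "C", "D"], 0.5),
        ],
    )
    def test_overlap_jaccard(self, edge_a, edge_b, expected):
        results = [
            EnrichmentResult("s1", 3, 0.5, 3, 0.01, leading_edge=edge_a),
            EnrichmentResult("s2", 3, 0.5, 3, 0.01, leading_edge=edge_b),
        ]
        mat = leading_edge_overlap(results)
        assert mat.loc["s1", "s2"] == pytest.approx(expected)
        assert mat.loc["s1", "s1"] == 1.0
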