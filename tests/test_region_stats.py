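"""Region combination: ACF, Stouffer–Liptak, Sidak, change summaries."""

import numpy as np
import pytest
from scipy.stats import norm

from dmrank.io import Region, RegionSet
from dmrank.region_stats import (
    AcfEstimate,
    call_dmrs,
    estimate_acf,
    map_probes_to_regions,
    region_change_summary,
    sidak_correct,
    stouffer_liptak,
)

from conftest import make_dataset


class TestMapProbes:
    def test_half_open_convention(self, toy_dataset):
        regions = RegionSet(
            [Region("chr1", 100, 200, "in"), Region("chr1", 0, 100, "out")]
        )
        mapping, n_skipped = map_probes_to_regions(toy_dataset, regions)
        assert "in" in mapping and "out" not in mapping
        assert n_skipped == 1

    def test_overlapping_regions_share_probes(self, toy_dataset):
        regions = RegionSet(
            [Region("chr1", 0, 250, "r1"), Region("chr1", 150, 350, "r2")]
        )
        mapping, _ = map_probes_to_regions(toy_dataset, regions)
        # probe at 200 sits in both
        assert 1 in mapping["r1"] and 1 in mapping["r2"]


class TestEstimateAcf:
    def test_constant_z_gives_zero(self):
        pos = np.arange(100) * 10
        chrom = np.array(["chr1"] * 100, dtype=object)
        acf = estimate_acf(np.ones(100), chrom, pos, lag_bins=(0, 50, 100))
        assert np.all(acf.corr == 0.0)

    def test_iid_z_near_zero(self):
        rng = np.random.default_rng(123)
        n = 10_000
        pos = np.cumsum(rng.integers(50, 150, size=n))
        chrom = np.array(["chr1"] * n, dtype=object)
        acf = estimate_acf(rng.standard_normal(n), chrom, pos)
        assert np.all(np.abs(acf.corr) <= 0.05)

    def test_duplicated_adjacent_values_perfectly_correlated(self):
        # identical z at paired positions 10 bp apart -> corr 1 in the
        # bin covering distance 10
        z = np.repeat(np.random.default_rng(4).standard_normal(40), 2)
        pos = np.empty(80, dtype=np.int64)
        pos[0::2] = np.arange(40) * 10_000
        pos[1::2] = pos[0::2] + 10
        chrom = np.array(["chr1"] * 80, dtype=object)
        acf = estimate_acf(z, chrom, pos, lag_bins=(0, 20, 1000))
        assert acf.corr[0] == pytest.approx(1.0, abs=1e-12)

    def test_too_few_probes_rejected(self):
        with pytest.raises(ValueError):
            estimate_acf(np.array([1.0]), np.array(["chr1"], dtype=object),
                         np.array([1]))

    def test_corr_beyond_last_bin_is_zero(self):
        acf = AcfEstimate(lag_bins=(0, 10, 100), corr=np.array([0.9, 0.5]),
                          n_pairs=np.array([100, 100]))
        assert acf.corr_at(5) == 0.9
        assert acf.corr_at(50) == 0.5
        assert acf.corr_at(101) == 0.0
        assert acf.corr_at(0) == 0.9  # co-located probes


class TestStoufferLiptak:
    def test_singleton_identity(self):
        assert stouffer_liptak([0.03], np.array([[1.0]])) == pytest.approx(
            0.03, abs=1e-12
        )

    def test_four_independent_equal_p(self):
        p = stouffer_liptak([0.05] * 4, np.eye(4))
        assert p == pytest.approx(0.0005014583328204809, abs=1e-12)

    def test_complete_dependence_collapses(self):
        sigma = np.ones((5, 5))
        assert stouffer_liptak([0.07] * 5, sigma) == pytest.approx(0.07, abs=1e-10)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            stouffer_liptak([])

    def test_monotone_in_member_p(self):
        rng = np.random.default_rng(8)
        sigma = np.eye(4)
        p = rng.uniform(0.1, 0.9, 4)
        base = stouffer_liptak(p, sigma)
        p2 = p.copy()
        p2[2] *= 0.5
        assert stouffer_liptak(p2, sigma) <= base

    def test_nonpositive_sigma_sum_falls_back_to_independence(self):
        sigma = np.array([[1.0, -1.0], [-1.0, 1.0]])  # sums to 0
        assert stouffer_liptak([0.05, 0.05], sigma) == pytest.approx(
            stouffer_liptak([0.05, 0.05], np.eye(2)), abs=1e-15
        )


class TestSidak:
    def test_known_value(self):
        assert sidak_correct(0.01, 100, 1000) == pytest.approx(
            0.09561792499119559, abs=1e-12
        )

    def test_m_equal_one_is_identity(self):
        assert sidak_correct(0.2, 500, 500) == 0.2

    def test_small_p_linearization(self):
        p = 1e-8
        q = sidak_correct(p, 100, 10_000)  # m = 100
        assert q == pytest.approx(100 * p, rel=1e-2)

    def test_matches_naive_formula_over_grid(self):
        for p in (1e-16, 1e-8, 1e-3, 0.1, 0.5):
            for m in (1, 10, 1000, 10**6):
                q = sidak_correct(p, 1.0, float(m))
                naive = -np.expm1(m * np.log1p(-p))
                assert q == pytest.approx(max(naive, p), abs=1e-12)

    def test_monotone_in_p_and_m(self):
        qs = [sidak_correct(p, 100, 1000) for p in (0.001, 0.01, 0.1)]
        assert qs == sorted(qs)
        qm = [sidak_correct(0.01, 100, t) for t in (100, 1000, 10_000)]
        assert qm == sorted(qm)
        assert all(sidak_correct(p, 10, 1000) >= p for p in (1e-12, 0.01, 0.9))


class TestChangeSummary:
    def test_identical_groups_zero(self):
        ds = make_dataset(np.full((3, 4), 0.4), ["A", "A", "B", "B"])
        assert region_change_summary(ds, ("A", "B"), [0, 1, 2]) == (0.0, 0.0, 0.0)

    def test_single_probe(self):
        beta = np.array([[0.5, 0.5, 0.7, 0.7]])
        ds = make_dataset(beta, ["A", "A", "B", "B"])
        assert region_change_summary(ds, ("A", "B"), [0]) == pytest.approx(
            (0.2, 0.2, 0.2)
        )

    def test_three_probe_hand_constructed(self):
        # group medians chosen so d = {-0.1, 0.05, 0.3} per probe
        beta = np.array(
            [
                [0.5, 0.5, 0.4, 0.4],  # d = -0.1
                [0.20, 0.20, 0.25, 0.25],  # d = +0.05
                [0.1, 0.1, 0.4, 0.4],  # d = +0.3
            ]
        )
        ds = make_dataset(beta, ["A", "A", "B", "B"])
        out = region_change_summary(ds, ("A", "B"), [0, 1, 2])
        assert out == pytest.approx((-0.1, 0.05, 0.3))


class TestCallDmrs:
    def make_shifted(self, shift=0.3, n_probes=6, seed=0):
        rng = np.random.default_rng(seed)
        base = rng.uniform(0.2, 0.4, size=(n_probes, 1))
        noise = rng.normal(0, 0.02, size=(n_probes, 8))
        beta = np.clip(base + noise, 0, 1)
        beta[:, 4:] += shift  # group B higher
        return make_dataset(np.clip(beta, 0, 1), ["A"] * 4 + ["B"] * 4)

    def test_permissive_thresholds_return_everything(self, toy_dataset):
        regions = RegionSet([Region("chr1", 0, 400, "r1"), Region("chr2", 0, 100, "r2")])
        calls = call_dmrs(toy_dataset, regions, q_cutoff=1.0, min_abs_median_change=0.0)
        assert len(calls[("A", "B")]) == 2

    def test_direction_matches_shift_sign(self):
        ds = self.make_shifted()
        regions = RegionSet([Region("chr1", 0, 10_000, "all")])
        res = call_dmrs(ds, regions)[("A", "B")][0]
        assert res.direction == "B"
        assert res.change_median > 0
        assert res.q_b < res.q_a

    def test_no_probe_regions_rejected(self, toy_dataset):
        regions = RegionSet([Region("chrX", 0, 100, "r")])
        with pytest.raises(ValueError):
            call_dmrs(toy_dataset, regions)

    def test_single_probe_identity_sigma_degeneracy(self):
        # one probe per region and identical spans: region q must equal
        # the Sidak-corrected smaller directional probe p exactly
        rng = np.random.default_rng(21)
        n = 30
        beta = rng.uniform(0, 1, (n, 12))
        pos = np.arange(n) * 100_000  # far apart -> sigma is identity
        ds = make_dataset(beta, ["A"] * 6 + ["B"] * 6, pos=pos)
        regions = RegionSet(
            [Region("chr1", int(p), int(p) + 10, f"r{i}") for i, p in enumerate(pos)]
        )
        from dmrank.probe_stats import all_pairs_probe_tests

        table = all_pairs_probe_tests(ds)
        results = call_dmrs(ds, regions)[("A", "B")]
        by_name = {r.region.name: r for r in results}
        for i in range(n):
            r = by_name[f"r{i}"]
            row = table.iloc[i]
            p_min = min(row["p_a_greater"], row["p_b_greater"])
            # total span = 30 regions x 10 bp, each span 10 -> m = 30
            expected_q = sidak_correct(min(p_min, 1 - 1e-16), 10, 300)
            assert r.q == pytest.approx(expected_q, abs=1e-12)
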