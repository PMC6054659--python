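import numpy as np
import pytest

from tropiscan import simdata, sweepscan

from conftest import make_haplotypes, make_marker_map
from oracles import ehhs_string_oracle


class TestEhhsProfile:
    def test_unity_at_focal_marker(self, two_pop_haplotypes):
        h, _ = two_pop_haplotypes
        prof = sweepscan.ehhs_profile(h.restrict_population("A"), 300)
        assert prof.ehhs[prof.focal_index] == 1.0

    def test_identical_haplotypes_flat_profile(self):
        h = make_haplotypes(np.tile([0, 1, 0, 1, 1], (6, 1)))
        prof = sweepscan.ehhs_profile(h, 2)
        assert np.allclose(prof.ehhs, 1.0)

    def test_matches_string_grouping_oracle(self):
        strings = ["01011", "01010", "11011", "01011", "10110", "01110"]
        alleles = np.array([[int(c) for c in s] for s in strings], dtype=np.int8)
        h = make_haplotypes(alleles)
        focal = 2
        prof = sweepscan.ehhs_profile(h, focal)
        for x in range(5):
            want = ehhs_string_oracle(strings, focal, x)
            assert prof.ehhs[x] == pytest.approx(want, abs=1e-12)

    def test_monotone_nonincreasing_outward(self, two_pop_haplotypes):
        h, _ = two_pop_haplotypes
        sub = h.restrict_population("B")
        for focal in (50, 200, 400, 599):
            prof = sweepscan.ehhs_profile(sub, focal)
            f = prof.focal_index
            right = prof.ehhs[f:]
            left = prof.ehhs[: f + 1][::-1]
            assert np.all(np.diff(right[~np.isnan(right)]) <= 1e-12)
            assert np.all(np.diff(left[~np.isnan(left)]) <= 1e-12)

    def test_monomorphic_focal_flagged_degenerate(self):
        alleles = np.array(
            [[0, 0, 1], [0, 0, 0], [0, 1, 1], [0, 1, 0]], dtype=np.int8
        )
        h = make_haplotypes(alleles)
        prof = sweepscan.ehhs_profile(h, 0)
        assert prof.degenerate


class TestIes:
    @staticmethod
    def profile(positions, ehhs, focal_index):
        return sweepscan.EhhsProfile(
            focal_marker="m",
            focal_index=focal_index,
            positions_bp=np.asarray(positions, dtype=np.int64),
            ehhs=np.asarray(ehhs, dtype=float),
        )

    def test_rectangle(self):
        p = self.profile([1, 10_001, 20_001], [1.0, 1.0, 1.0], 0)
        assert sweepscan.ies(p) == pytest.approx(20_000.0)

    def test_hand_trapezoid_with_truncation(self):
        p = self.profile([1, 10_001, 20_001], [1.0, 0.5, 0.01], 0)
        assert sweepscan.ies(p) == pytest.approx(7_500.0, abs=1e-9)

    def test_degenerate_threshold(self):
        p = self.profile([1, 10_001], [1.0, 0.999], 0)
        assert sweepscan.ies(p, trunc_threshold=1.0) == 0.0
        p2 = self.profile([1, 10_001], [1.0, 1.0], 0)
        assert sweepscan.ies(p2, trunc_threshold=1.0) == pytest.approx(10_000.0)

    def test_single_marker_is_zero(self):
        p = self.profile([500], [1.0], 0)
        assert sweepscan.ies(p) == 0.0

    def test_large_gap_truncates(self):
        p = self.profile([1, 700_001, 710_001], [1.0, 1.0, 1.0], 0)
        assert sweepscan.ies(p, max_gap_bp=500_000) == 0.0


class TestRsb:
    def test_equal_ies_gives_zero(self):
        m = make_marker_map([1000, 2000, 3000])
        i = np.array([5.0, 7.0, 9.0])
        table = sweepscan.rsb(i, i, m, total_tail=0.5)
        assert np.allclose(table.ln_rsb_raw, 0.0)

    def test_ln_e_ratio(self):
        m = make_marker_map([1000, 2000, 3000])
        a = np.array([5.0, 7.0 * np.e, 9.0])
        b = np.array([5.0, 7.0, 9.0])
        table = sweepscan.rsb(a, b, m, total_tail=0.5)
        assert table.ln_rsb_raw[1] == pytest.approx(1.0)

    def test_zero_ies_excluded_with_reason(self):
        m = make_marker_map([1000, 2000, 3000])
        a = np.array([5.0, 0.0, 9.0])
        b = np.array([5.0, 7.0, 9.0])
        table = sweepscan.rsb(a, b, m, total_tail=0.5)
        assert table.excluded_reason[1] == "zero-iES"
        assert np.isnan(table.ln_rsb_raw[1])

    def test_marker_mismatch_is_an_error(self):
        m = make_marker_map([1000, 2000, 3000])
        with pytest.raises(ValueError):
            sweepscan.rsb(np.ones(2), np.ones(3), m)

    def test_sweep_makes_raw_rsb_negative_at_focal(self):
        hits = 0
        n = 12
        for seed in range(n):
            spec = simdata.SweepSpec(
                pop="B", focal_marker_index=150, core_length_bp=1_000_000,
                carrier_freq=0.9,
            )
            cfg = simdata.SimulationConfig(
                n_individuals=30, n_markers=300, chrom_length_bp=18_000_000,
                seed=seed, sweep=spec,
            )
            h, _, _ = simdata.simulate_dataset(cfg)
            pa = sweepscan.ehhs_profile(
                h.restrict_population("A"), 150, stop_threshold=0.05
            )
            pb = sweepscan.ehhs_profile(
                h.restrict_population("B"), 150, stop_threshold=0.05
            )
            ia, ib = sweepscan.ies(pa), sweepscan.ies(pb)
            if ia > 0 and ib > 0 and np.log(ia / ib) < 0:
                hits += 1
        assert hits >= 0.8 * n


class TestStandardize:
    def test_identity_when_already_standardized(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=5000)
        x = (x - np.median(x)) / np.std(x, ddof=1)
        z = sweepscan.standardize_scores(x)
        assert np.allclose(z, x, atol=1e-9)

    def test_affine_invariance(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=500)
        assert np.allclose(
            sweepscan.standardize_scores(x),
            sweepscan.standardize_scores(2.0 * x + 3.0),
        )

    def test_median_zero_sd_one(self):
        # odd sample size so the median is an element and maps to exactly 0
        rng = np.random.default_rng(2)
        z = sweepscan.standardize_scores(rng.normal(size=1001))
        assert np.median(z) == 0.0
        assert np.std(z, ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_zero_sd_is_an_error(self):
        with pytest.raises(ValueError):
            sweepscan.standardize_scores(np.ones(10))


class TestSelectSignificant:
    def test_all_equal_none_flagged(self):
        flags = sweepscan.select_significant(np.ones(100))
        assert not flags.any()

    def test_quantile_arithmetic_1_to_1000(self):
        scores = np.arange(1, 1001, dtype=float)
        flags = sweepscan.select_significant(scores, total_tail=0.01)
        assert set(scores[flags]) == {1, 2, 3, 4, 5, 996, 997, 998, 999, 1000}

    def test_vanishing_tail_empty(self):
        scores = np.arange(1, 1001, dtype=float)
        flags = sweepscan.select_significant(scores, total_tail=1e-9)
        assert not flags.any()

    def test_one_sided_modes(self):
        scores = np.arange(1, 101, dtype=float)
        lo = sweepscan.select_significant(scores, 0.05, sides="lower")
        hi = sweepscan.select_significant(scores, 0.05, sides="upper")
        assert scores[lo].max() < scores[hi].min()


class TestBuildIntervals:
    def run(self, pos_mb, flags, scores, **kw):
        m = make_marker_map([int(p * 1e6) for p in pos_mb])
        return sweepscan.build_intervals(
            np.asarray(flags), np.asarray(scores, dtype=float), m, **kw
        )

    def test_single_snp_no_interval(self):
        out = self.run([1.0, 5.0], [True, False], [3.0, 0.0])
        assert out == []

    def test_two_snps_too_far_apart(self):
        out = self.run([1.0, 3.0], [True, True], [3.0, 3.0])
        assert out == []

    def test_hand_clustering(self):
        out = self.run(
            [1.0, 1.5, 1.9, 4.0],
            [True, True, True, True],
            [-3.0, -3.5, -2.8, -4.0],
        )
        assert len(out) == 1
        iv = out[0]
        assert (iv.start_bp, iv.end_bp, iv.n_snps) == (1_000_000, 1_900_000, 3)
        assert iv.direction == "B"

    def test_sign_change_splits_cluster(self):
        out = self.run(
            [1.0, 1.2, 1.4, 1.6],
            [True, True, True, True],
            [-3.0, -3.0, 3.0, 3.0],
        )
        assert len(out) == 2
        assert {iv.direction for iv in out} == {"A", "B"}


class TestScanCalibration:
    def test_null_flagged_fraction_matches_tail(self, two_pop_haplotypes):
        h, _ = two_pop_haplotypes
        table, _ = sweepscan.scan_rsb(h, "A", "B")
        z = table.ln_rsb_std.to_numpy()
        finite = np.sort(z[np.isfinite(z)])
        # expected count from order statistics: for distinct scores the strict
        # tail rule flags exactly floor(0.005 n) per side
        n = len(finite)
        assert len(np.unique(finite)) == n
        expected = 2 * int(np.floor(0.005 * n))
        assert int(table.significant.sum()) == expected
        # with continuous scores, the count is within one SNP of 1% of the scan
        assert expected == pytest.approx(0.01 * len(finite), abs=1.0)

    def test_identical_populations_only_tail_artifacts(self, two_pop_haplotypes):
        h, _ = two_pop_haplotypes
        a = h.restrict_population("A")
        ies_a = sweepscan.ies_scan(a)
        table = sweepscan.rsb(ies_a, ies_a.copy(), h.markers)
        assert int(table.significant.sum()) == 0
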