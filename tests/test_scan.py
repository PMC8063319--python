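import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from poolscan import scan
from poolscan.scan import (KinshipModel, LocalScoreConfig, Region,
                           binomial_excess_test, build_kinship,
                           calibrate_threshold, call_regions, choose_xi,
                           flk_test, lindley_track, lk_test, match_regions)

from conftest import make_snp_table


def star_model(c=0.1, pools=("pool0", "pool1", "pool2")):
    return KinshipModel(pools=list(pools), outgroup=pools[-1],
                        distances=np.zeros((3, 3)),
                        branch_lengths=np.full(3, c), tested=list(pools))


class TestKinship:
    def test_three_point_equal_distances(self):
        d = 0.3
        branches = scan._three_point_branches(
            np.array([[0, d, d], [d, 0, d], [d, d, 0]], float),
            ["a", "b", "o"], "o")
        np.testing.assert_allclose(branches, d / 2)

    def test_three_point_asymmetric(self):
        D = np.zeros((3, 3))
        D[0, 1] = D[1, 0] = 0.2   # d_AB
        D[0, 2] = D[2, 0] = 0.4   # d_AO
        D[1, 2] = D[2, 1] = 0.4   # d_BO
        branches = scan._three_point_branches(D, ["a", "b", "o"], "o")
        np.testing.assert_allclose(branches, [0.1, 0.1, 0.3])

    def test_build_kinship_on_divergent_data(self, small_genome):
        _config, _dataset, _truth, snps = small_genome
        model = build_kinship(snps, "pool2")
        assert model.F.shape == (3, 3)
        assert np.all(np.diag(model.F) > 0)
        # rooted star: no shared drift -> off-diagonal zero
        assert np.all(model.F[~np.eye(3, dtype=bool)] == 0)
        reduced = build_kinship(snps, "pool2", include_outgroup=False)
        assert reduced.F.shape == (2, 2)

    def test_undiverged_pools_raise(self):
        rng = np.random.default_rng(0)
        p = np.tile(rng.uniform(0.2, 0.8, 500)[:, None], (1, 3))
        snps = make_snp_table(p, depths=np.full((500, 3), 1e6))
        with pytest.raises(ValueError, match="singular|branch"):
            build_kinship(snps, "pool2")

    def test_needs_enough_snps(self):
        snps = make_snp_table(np.random.default_rng(1).uniform(0, 1, (50, 3)))
        with pytest.raises(ValueError, match="100 SNPs"):
            build_kinship(snps, "pool2")


class TestLK:
    def test_equal_theta_self_normalises(self):
        # all SNPs identical -> T = n_pop - 1 everywhere
        snps = make_snp_table([[0.9, 0.1, 0.5]] * 4)
        out = lk_test(snps)
        np.testing.assert_allclose(out["T_LK"], 2.0)

    def test_double_mean_theta(self):
        # one SNP with theta t, one clamped to 0: mean t/2, so T = 2*t/(t/2) = 4
        snps = make_snp_table([[1.0, 0.0, 1.0], [0.5, 0.5, 0.5]])
        out = lk_test(snps)
        assert out.loc[0, "T_LK"] == pytest.approx(4.0)
        assert out.loc[0, "p_LK"] == pytest.approx(sps.chi2.sf(4.0, 2))
        assert out.loc[0, "p_LK"] == pytest.approx(0.1353, abs=5e-4)

    def test_negative_theta_clamps_to_zero(self):
        snps = make_snp_table([[1.0, 0.0, 1.0], [0.5, 0.5, 0.5]])
        out = lk_test(snps)
        assert out.loc[1, "T_LK"] == 0.0
        assert out.loc[1, "p_LK"] == 1.0

    def test_all_monomorphic_raises(self):
        snps = make_snp_table([[0.5, 0.5, 0.5]] * 3)
        with pytest.raises(ValueError, match="not positive"):
            lk_test(snps)


class TestFLK:
    def test_null_point_gives_zero_statistic(self):
        snps = make_snp_table([[0.4, 0.4, 0.4]])
        out = flk_test(snps, star_model())
        assert out.loc[0, "T_FLK"] == pytest.approx(0.0, abs=1e-12)
        assert out.loc[0, "p_FLK"] == pytest.approx(1.0)

    def test_hand_value_on_star_kinship(self):
        # F = 0.1*I, p = (0.5, 0.5, 0.8): p0 = 0.6, resid (-.1,-.1,.2)
        # T = (0.01+0.01+0.04)/0.1 / (0.6*0.4) = 0.6/0.24 = 2.5
        snps = make_snp_table([[0.5, 0.5, 0.8]])
        out = flk_test(snps, star_model(c=0.1))
        assert out.loc[0, "p0"] == pytest.approx(0.6)
        assert out.loc[0, "T_FLK"] == pytest.approx(2.5)
        assert out.loc[0, "p_FLK"] == pytest.approx(sps.chi2.sf(2.5, 2))

    def test_boundary_ancestral_frequency_dropped(self):
        snps = make_snp_table([[0.0, 0.0, 0.0], [0.5, 0.5, 0.8]])
        out = flk_test(snps, star_model())
        assert np.isnan(out.loc[0, "T_FLK"]) and np.isnan(out.loc[0, "p_FLK"])
        assert np.isfinite(out.loc[1, "T_FLK"])

    def test_statistic_is_chi2_under_ideal_null(self):
        """True frequencies, known star F: T_FLK ~ chi-square(2) at m=1e4."""
        rng = np.random.default_rng(42)
        m, c = 10_000, 0.01
        p0 = rng.uniform(0.35, 0.65, m)
        p = p0[:, None] + rng.normal(0.0, 1.0, (m, 3)) * np.sqrt(
            c * (p0 * (1 - p0))[:, None])
        assert (p > 0).all() and (p < 1).all()  # no clipping distortion
        snps = make_snp_table(p, depths=np.full((m, 3), 1e9))
        out = flk_test(snps, star_model(c=c))
        ks = sps.kstest(out["p_FLK"], "uniform")
        assert ks.pvalue > 0.01
        ks_t = sps.kstest(out["T_FLK"], sps.chi2(2).cdf)
        assert ks_t.pvalue > 0.01

    def test_rank_agreement_with_lk_under_equal_branches(self):
        """F = c*I with equal depths orders SNPs exactly like LK."""
        rng = np.random.default_rng(7)
        m = 2000
        p0 = rng.uniform(0.2, 0.8, m)
        p = np.clip(p0[:, None] + rng.normal(0, 0.12, (m, 3)), 0.01, 0.99)
        # effectively exact frequencies: the comparison is between the test
        # statistics themselves, not the finite-depth sampling corrections
        snps = make_snp_table(p, depths=np.full((m, 3), 1e4))
        t_flk = flk_test(snps, star_model(c=0.05))["T_FLK"]
        t_lk = lk_test(snps)["T_LK"]
        rho = sps.spearmanr(t_flk, t_lk).statistic
        assert rho > 0.99


class TestChooseXi:
    def test_constant_pvalues(self):
        assert choose_xi([0.1] * 10) == pytest.approx(1.0)

    def test_uniform_grid_against_sorting_oracle(self):
        p = np.arange(1, 100) / 100.0
        scores = np.sort(-np.log10(p))
        # linear-interpolation quantile computed by hand from the order stats
        h = (len(scores) - 1) * 0.85
        lo, hi = int(np.floor(h)), int(np.ceil(h))
        expected = scores[lo] + (h - lo) * (scores[hi] - scores[lo])
        assert choose_xi(p, 0.85) == pytest.approx(expected)

    def test_default_quantile_is_85(self):
        assert LocalScoreConfig().xi_quantile == 0.85

    def test_xi_between_mean_and_max(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=1000)
        xi = choose_xi(p)
        s = -np.log10(p)
        assert s.mean() <= xi <= s.max()

    def test_rejects_bad_pvalues(self):
        with pytest.raises(ValueError):
            choose_xi([])
        with pytest.raises(ValueError):
            choose_xi([0.5, 0.0])


class TestLindley:
    def test_all_p_one_gives_zero_track(self):
        track = lindley_track(np.ones(10), xi=0.5)
        np.testing.assert_allclose(track, 0.0)

    def test_hand_recursion(self):
        p = 10.0 ** -np.array([2.0, 0.5, 3.0])
        np.testing.assert_allclose(lindley_track(p, xi=1.0), [1.0, 0.5, 2.5])

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.integers(1, 200), st.integers(0, 10_000),
           st.floats(0.1, 3.0))
    def test_max_equals_best_clipped_subinterval(self, n, seed, xi):
        """Brute-force oracle: max h = max over [i,j] of clipped segment sums."""
        rng = np.random.default_rng(seed)
        p = rng.uniform(1e-4, 1.0, n)
        scores = -np.log10(p) - xi
        best = 0.0
        for i in range(n):
            acc = 0.0
            for j in range(i, n):
                acc += scores[j]
                best = max(best, acc)
        track = lindley_track(p, xi)
        assert track.max() == pytest.approx(best, abs=1e-9)
        assert track.min() >= 0.0 and track[0] == pytest.approx(
            max(0.0, scores[0]))


class TestThreshold:
    def test_alpha_one_limit_is_minimum_maximum(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=500)
        xi = choose_xi(p)
        t_min = calibrate_threshold(p, xi, alpha=1.0, B=200, seed=1)
        t_05 = calibrate_threshold(p, xi, alpha=0.05, B=200, seed=1)
        assert t_min <= t_05

    def test_self_calibration_under_iid_pvalues(self):
        """Chromosomes calibrated against their own i.i.d. resamples produce
        false positives at rate ~ alpha (the chromosome-wide error contract)."""
        rng = np.random.default_rng(2024)
        n, trials, alpha = 2000, 400, 0.05
        hits = 0
        for _ in range(trials):
            p = rng.uniform(size=n)
            xi = choose_xi(p)
            thr = calibrate_threshold(p, xi, alpha=alpha, B=300,
                                      seed=int(rng.integers(2**31 - 1)))
            hits += lindley_track(p, xi).max() >= thr
        rate = hits / trials
        se = np.sqrt(alpha * (1 - alpha) / trials)
        assert abs(rate - alpha) <= 3 * se

    def test_small_b_rejected(self):
        with pytest.raises(ValueError):
            calibrate_threshold(np.full(10, 0.5), 1.0, B=50)


class TestCallRegions:
    def test_hand_trace(self):
        h = np.array([0.0, 1.0, 0.5, 2.5, 0.0])
        pos = np.array([100, 200, 300, 400, 500])
        regions = call_regions(h, threshold=2.0, positions=pos)
        assert len(regions) == 1
        r = regions[0]
        assert (r.start_index, r.end_index) == (1, 3)
        assert (r.start_bp, r.end_bp) == (200, 400)
        assert r.peak == pytest.approx(2.5) and r.peak_bp == 400

    def test_threshold_above_max_gives_nothing(self):
        h = np.array([0.0, 1.0, 0.5])
        assert call_regions(h, 2.0, [1, 2, 3]) == []

    def test_two_excursions_give_two_regions(self):
        h = np.array([1.0, 3.0, 0.0, 2.5, 2.0])
        regions = call_regions(h, 2.0, [10, 20, 30, 40, 50])
        assert len(regions) == 2
        assert regions[0].start_bp == 10 and regions[1].start_bp == 40
        assert regions[1].end_bp == 50  # runs to the chromosome end

    def test_peak_tie_takes_first_index(self):
        h = np.array([2.0, 1.0, 2.0])
        regions = call_regions(h, 2.0, [1, 2, 3])
        assert regions[0].peak_bp == 1

    def test_zero_threshold_rejected(self):
        with pytest.raises(ValueError):
            call_regions(np.array([1.0]), 0.0, [1])


class TestRegionsMatching:
    def r(self, a, b, chrom="c1"):
        return Region(chrom=chrom, start_index=0, end_index=0, start_bp=a,
                      end_bp=b, peak=1.0, peak_index=0, peak_bp=a)

    def test_overlap_and_discordance_counts(self):
        flk = [self.r(100, 200), self.r(500, 600)]
        lk = [self.r(150, 250), self.r(900, 950)]
        m = match_regions(flk, lk)
        assert m == {"matched": 1, "only_a": 1, "only_b": 1, "union": 3}

    def test_different_chromosomes_do_not_match(self):
        m = match_regions([self.r(1, 10, "c1")], [self.r(1, 10, "c2")])
        assert m["matched"] == 0 and m["union"] == 2


class TestBinomialExcess:
    def test_zero_observed_is_one(self):
        assert binomial_excess_test(0, 30, 0.186) == pytest.approx(1.0)

    def test_matches_exact_binomial_oracle(self):
        expected = sps.binomtest(11, 30, 0.186, alternative="greater").pvalue
        assert binomial_excess_test(11, 30, 0.186) == pytest.approx(expected)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            binomial_excess_test(31, 30, 0.1)
        with pytest.raises(ValueError):
            binomial_excess_test(1, 30, 1.5)


class TestScanGenome:
    def test_fpr_matches_alpha_without_linkage(self):
        """Independent SNPs: the whole scan pipeline calls ~alpha regions/chrom."""
        rng = np.random.default_rng(99)
        n_chrom, n = 150, 800
        c = 0.05
        p0 = rng.uniform(0.25, 0.75, (n_chrom * n))
        p = np.clip(p0[:, None] + rng.normal(0, 1, (n_chrom * n, 3))
                    * np.sqrt(c * (p0 * (1 - p0))[:, None]), 1e-3, 1 - 1e-3)
        chrom = np.repeat([f"chr{i}" for i in range(n_chrom)], n)
        pos = np.tile(np.arange(1, n + 1), n_chrom)
        snps = make_snp_table(p, depths=np.full((n_chrom * n, 3), 1e9),
                              chrom=chrom, pos=pos)
        res = scan.scan_genome(snps, star_model(c=c),
                               LocalScoreConfig(alpha=0.05, B=200), seed=17)
        rate = len(res["regions"]["flk"]) / n_chrom
        se = np.sqrt(0.05 * 0.95 / n_chrom)
        assert abs(rate - 0.05) <= 3 * se + 0.01
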