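"""Mismatch distributions, expansion fits, Fu's Fs, clock conversions."""

import math

import numpy as np
import pytest

from conftest import make_alignment
from sierrapop.demography import (
    RateError, RateModel, SizeError, census_from_catch, ewens_k_pmf,
    expected_mismatch_spatial, expected_mismatch_sudden,
    fit_demographic_expansion, fit_spatial_expansion, fu_fs,
    fu_fs_from_summary, histogram_from_diff_matrix, mismatch_histogram,
    tau_to_time, theta_to_N,
)
from sierrapop.demography import _fit_spatial_core, _fit_sudden_core
from sierrapop.simulate import Scenario, simulate_pairwise_differences, simulate_sample


class TestMismatchHistogram:
    def test_monomorphic_all_pairs_class_zero(self):
        hist = mismatch_histogram(make_alignment(["ACGT" * 10] * 5))
        assert hist.counts[0] == 10 and hist.n_pairs == 10

    def test_two_haplotype_combinatorics(self):
        # counts (3, 2), d = 4 differing sites -> class 4 has 3*2 pairs,
        # class 0 has C(3,2)+C(2,2) = 4 pairs
        a = "A" * 20
        b = "C" * 4 + "A" * 16
        hist = mismatch_histogram(make_alignment([a, a, a, b, b]))
        assert hist.counts[0] == 4 and hist.counts[4] == 6
        assert hist.counts.sum() == hist.n_pairs == 10

    def test_too_small_sample(self):
        with pytest.raises(SizeError):
            mismatch_histogram(make_alignment(["ACGT", "ACGA"]))


class TestExpectedCurves:
    @pytest.mark.parametrize("args", [(12, 1, 500), (0.5, 2, 5), (5, 0, 99999)])
    def test_sudden_curve_normalised(self, args):
        assert expected_mismatch_sudden(400, *args).sum() == \
            pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("args", [(9, 3, 50), (10, 5, 1e4), (2, 0.5, 0.2)])
    def test_spatial_curve_normalised(self, args):
        assert expected_mismatch_spatial(500, *args).sum() == \
            pytest.approx(1.0, abs=1e-6)

    def test_tau_zero_is_equilibrium_geometric(self):
        F = expected_mismatch_sudden(50, 0.0, 3.0, 500.0)
        j = np.arange(50)
        geo = 3.0 ** j / 4.0 ** (j + 1)
        assert np.allclose(F, geo, atol=1e-12)

    def test_spatial_large_M_matches_pure_expansion(self):
        Fs = expected_mismatch_spatial(100, 10, 1, 1e4)
        Fd = expected_mismatch_sudden(100, 10, 1, 99999)
        assert np.max(np.abs(Fs - Fd)) < 5e-4


class TestFitters:
    def test_noise_free_recovery(self):
        F = expected_mismatch_sudden(60, 10, 1, 500)
        ssd, tau, t0, t1 = _fit_sudden_core(F)
        assert tau == pytest.approx(10, abs=0.1)
        assert t0 == pytest.approx(1, abs=0.1)
        assert ssd < 1e-10

    def test_noise_free_spatial_recovery(self):
        F = expected_mismatch_spatial(60, 9, 3, 50)
        ssd, tau, theta, M = _fit_spatial_core(F)
        assert tau == pytest.approx(9, abs=0.3)
        assert theta == pytest.approx(3, abs=0.5)
        assert ssd < 1e-9

    def test_expansion_fit_with_bootstrap(self):
        rng = np.random.default_rng(5)
        sc = Scenario(kind="sudden_expansion", tau=10, theta0=1, theta1=500,
                      n=50, seed=0)
        hist = histogram_from_diff_matrix(simulate_pairwise_differences(sc, rng))
        fit = fit_demographic_expansion(hist, n_boot=100, seed=2)
        assert 6 < fit.tau < 14
        assert fit.tau_ci95[0] < fit.tau < fit.tau_ci95[1]
        assert 0.0 <= fit.p_ssd <= 1.0

    def test_spatial_parameter_recovery_within_ci(self):
        rng = np.random.default_rng(11)
        hits = 0
        reps = 10
        for _ in range(reps):
            sc = Scenario(kind="continent_island", tau=9, theta=3, M=50,
                          n=50, seed=0)
            hist = histogram_from_diff_matrix(
                simulate_pairwise_differences(sc, rng))
            fit = fit_spatial_expansion(hist, n_boot=60, seed=3)
            if fit.tau_ci95[0] <= 9 <= fit.tau_ci95[1]:
                hits += 1
        assert hits >= 7

    def test_constant_size_fits_worse_and_tau_unstable(self):
        """Equilibrium (often multimodal) histograms leave more residual SSD
        than expansion histograms, and τ̂ is unstable across replicates."""
        rng = np.random.default_rng(3)
        ssd_c, ssd_e, taus_c = [], [], []
        for _ in range(8):
            hc = histogram_from_diff_matrix(simulate_pairwise_differences(
                Scenario(kind="constant", theta=4, n=50, seed=0), rng))
            fc = fit_demographic_expansion(hc, n_boot=0)
            ssd_c.append(fc.ssd)
            taus_c.append(fc.tau)
            he = histogram_from_diff_matrix(simulate_pairwise_differences(
                Scenario(kind="sudden_expansion", tau=10, theta0=1,
                         theta1=500, n=50, seed=0), rng))
            ssd_e.append(fit_demographic_expansion(he, n_boot=0).ssd)
        assert np.mean(ssd_c) > np.mean(ssd_e)
        assert np.std(taus_c) / max(np.mean(taus_c), 1e-9) > 0.2


class TestFuFs:
    def test_matches_crp_enumeration_small_n(self):
        """Stirling-number route equals an independent Chinese-restaurant
        forward recursion for every (n <= 8, theta)."""
        def crp_pmf(n, theta):
            dist = {1: 1.0}
            for m in range(1, n):
                new = {}
                for k, p in dist.items():
                    new[k] = new.get(k, 0.0) + p * m / (m + theta)
                    new[k + 1] = new.get(k + 1, 0.0) + p * theta / (m + theta)
                dist = new
            return dist

        for n in range(2, 9):
            for theta in (0.3, 1.0, 2.7, 10.0):
                pmf = ewens_k_pmf(n, theta)
                ref = crp_pmf(n, theta)
                for k in range(1, n + 1):
                    assert pmf[k] == pytest.approx(ref.get(k, 0.0), abs=1e-9)

    def test_fs_example_frozen_value(self):
        # n=5, theta=1, nh=2: P(K>=2) = 0.8 by direct enumeration
        res = fu_fs_from_summary(5, 2, 1.0)
        assert res.s_prime == pytest.approx(0.8, abs=1e-12)
        assert res.fs == pytest.approx(math.log(4.0), abs=1e-12)

    def test_monomorphic_flagged(self):
        res = fu_fs_from_summary(10, 1, 0.0)
        assert res.flagged == "s_prime_one" and res.fs == math.inf

    def test_expansion_vs_constant_contrast(self):
        aln_e, _ = simulate_sample(Scenario(kind="sudden_expansion", tau=10,
                                            theta0=1, theta1=500, n=30, seed=3))
        aln_c, _ = simulate_sample(Scenario(kind="constant", theta=5, n=30,
                                            seed=3))
        fs_e = fu_fs(aln_e, n_sim=200, seed=1)
        fs_c = fu_fs(aln_c, n_sim=200, seed=1)
        assert fs_e.fs < -5 and fs_e.p < 0.05
        assert fs_e.fs < fs_c.fs
        assert fs_c.p > 0.01

    def test_small_sample_rejected(self):
        with pytest.raises(SizeError):
            fu_fs(make_alignment(["ACGT"] * 3))


class TestConversions:
    def test_table_values_reproduced(self):
        rm = RateModel()
        assert tau_to_time(13.4, rm)[2] == pytest.approx(287.2, abs=0.05)
        assert tau_to_time(11.5, rm)[2] == pytest.approx(246.5, abs=0.05)
        assert theta_to_N(255.3, rm) == pytest.approx(2.7e6, rel=0.02)
        assert round(theta_to_N(5.1, rm), -3) == 55_000

    def test_zero_maps_to_zero(self):
        assert tau_to_time(0.0)[2] == 0.0
        assert theta_to_N(0.0) == 0.0

    def test_linearity_and_generation_scaling(self):
        rm1 = RateModel()
        rm2 = RateModel(generation_years=4.0)
        g1, y1, _ = tau_to_time(5.0, rm1)
        g2, y2, _ = tau_to_time(5.0, rm2)
        assert g2 == pytest.approx(g1 / 2.0)     # u doubles with generation
        assert y2 == pytest.approx(y1)           # years unchanged: u ~ gen
        assert tau_to_time(10.0, rm1)[1] == pytest.approx(2 * y1)

    def test_invalid_rate_model(self):
        with pytest.raises(RateError):
            RateModel(rate_per_site_per_year=0.0)

    def test_census_arithmetic(self):
        assert census_from_catch(10_000, 450) == pytest.approx(22.2e6, rel=2e-3)
        assert census_from_catch(450, 450) == pytest.approx(1.0e6)
        assert census_from_catch(1, 500) == pytest.approx(2000)
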