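"""Umbrella-window extraction, WHAM, Bayesian bootstrap and K_d."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lipidkinetics.pmf import (
    KB_KJ_PER_MOL_K,
    STANDARD_STATE_VOLUME_NM3,
    PMFProfile,
    UmbrellaWindow,
    bayesian_bootstrap_pmf,
    estimate_kd,
    extract_windows,
    sample_biased_synthetic,
    wham_1d,
)


def double_well(x):
    """W(x) = 10 (x-1)^2 (x-2)^2 kJ/mol: minima at 1 and 2, barrier at 1.5."""
    return 10.0 * (np.asarray(x) - 1.0) ** 2 * (np.asarray(x) - 2.0) ** 2


class TestExtractWindows:
    def test_monotone_ramp_yields_fifty_centers(self):
        rc = np.linspace(0.0, 2.45, 1000)
        centers = extract_windows(rc, spacing_nm=0.05)
        assert len(centers) == 50
        assert centers[0] == (0.0, 0)
        assert centers[-1][0] == pytest.approx(2.45)

    def test_first_crossing_frame_chosen_despite_backtrack(self):
        rc = np.array([0.0, 0.06, 0.03, 0.08, 0.12])
        centers = extract_windows(rc, spacing_nm=0.05)
        # 0.05 first crossed at frame 1; 0.10 first crossed at frame 4
        assert centers[1] == (pytest.approx(0.05), 1)
        assert centers[2] == (pytest.approx(0.10), 4)

    def test_window_count_cap_respected(self):
        rc = np.linspace(0.0, 3.0, 500)
        assert len(extract_windows(rc, spacing_nm=0.05, n_windows=50)) == 50

    def test_descending_pulls_supported(self):
        rc = np.linspace(2.0, 1.0, 300)
        centers = extract_windows(rc, spacing_nm=0.1)
        assert centers[1][0] == pytest.approx(1.9)

    def test_short_span_rejected(self):
        with pytest.raises(ValueError, match="span"):
            extract_windows([1.0, 1.01], spacing_nm=0.05)


class TestBiasedSampler:
    def test_flat_potential_gives_harmonic_moments(self):
        k, T = 1000.0, 323.0
        wins = sample_biased_synthetic(
            lambda x: np.zeros_like(x), [1.0], force_constant=k,
            n_per_window=20_000, temperature_K=T, seed=3,
        )
        s = wins[0].samples_nm
        var = KB_KJ_PER_MOL_K * T / k
        assert abs(s.mean() - 1.0) <= 3 * np.sqrt(var / len(s))
        assert s.var() == pytest.approx(var, rel=0.05)
        assert wins[0].harmonic_sanity_flag(T)

    def test_harmonic_potential_combines_gaussians(self):
        # W = k0/2 (x-a)^2 with bias k/2 (x-c)^2 is Gaussian with
        # mean (k0 a + k c)/(k0+k), variance kT/(k0+k)
        k0, a, k, c, T = 400.0, 0.8, 1000.0, 1.2, 323.0
        wins = sample_biased_synthetic(
            lambda x: 0.5 * k0 * (np.asarray(x) - a) ** 2, [c],
            force_constant=k, n_per_window=20_000, temperature_K=T, seed=4,
        )
        s = wins[0].samples_nm
        mu = (k0 * a + k * c) / (k0 + k)
        var = KB_KJ_PER_MOL_K * T / (k0 + k)
        assert s.mean() == pytest.approx(mu, abs=3 * np.sqrt(var / len(s)))
        assert s.var() == pytest.approx(var, rel=0.05)

    def test_identical_seed_identical_samples(self):
        a = sample_biased_synthetic(double_well, [1.0, 1.5], n_per_window=100, seed=9)
        b = sample_biased_synthetic(double_well, [1.0, 1.5], n_per_window=100, seed=9)
        for wa, wb in zip(a, b):
            assert np.array_equal(wa.samples_nm, wb.samples_nm)

    def test_non_finite_potential_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            sample_biased_synthetic(
                lambda x: np.where(np.asarray(x) > 0.5, np.inf, 0.0), [1.0],
                n_per_window=100,
            )


class TestWham:
    def test_single_unbiased_window_flat_within_noise(self):
        rng = np.random.default_rng(0)
        # nearly zero force constant = unbiased sampling of a flat potential
        win = UmbrellaWindow(0.5, 1e-9, rng.uniform(0.0, 1.0, 200_000))
        prof = wham_1d([win], n_bins=20)
        assert np.nanmax(np.abs(prof.w_kj_mol)) < 0.15

    def test_single_window_equals_boltzmann_inversion(self):
        """In the one-window limit WHAM reduces to -kT log(histogram)."""
        wins = sample_biased_synthetic(double_well, [1.5], n_per_window=50_000, seed=2)
        prof = wham_1d(wins, n_bins=40)
        kT = KB_KJ_PER_MOL_K * prof.temperature_K
        counts, edges = np.histogram(wins[0].samples_nm, bins=40,
                                     range=(wins[0].samples_nm.min(), wins[0].samples_nm.max()))
        centers = 0.5 * (edges[:-1] + edges[1:])
        bias = 0.5 * wins[0].force_constant * (centers - 1.5) ** 2
        direct = -kT * np.log(np.where(counts > 0, counts, np.nan)) - bias
        direct -= np.nanmin(direct)
        # re-anchor both on their common minimum support
        ok = np.isfinite(direct) & np.isfinite(prof.w_kj_mol)
        assert np.nanmax(np.abs(prof.w_kj_mol[ok] - direct[ok])) < 0.2

    def test_double_well_recovered(self):
        centers = [0.3 + 0.05 * i for i in range(50)]
        wins = sample_biased_synthetic(double_well, centers, n_per_window=2000, seed=11)
        prof = wham_1d(wins)
        truth = double_well(prof.xi_nm)
        ok = np.isfinite(prof.w_kj_mol)
        truth = truth - truth[ok].min()
        rms = np.sqrt(np.mean((prof.w_kj_mol[ok] - truth[ok]) ** 2))
        assert rms < 0.5
        assert np.nanmin(prof.w_kj_mol) == pytest.approx(0.0, abs=1e-12)

    def test_gauge_invariance_under_constant_offset(self):
        """Adding a constant to the true potential leaves the anchored
        profile unchanged (same seed, same samples modulo the constant)."""
        centers = [0.8 + 0.05 * i for i in range(10)]
        a = sample_biased_synthetic(double_well, centers, n_per_window=2000, seed=5)
        b = sample_biased_synthetic(
            lambda x: double_well(x) + 37.0, centers, n_per_window=2000, seed=5
        )
        grid = (0.6, 1.6)
        pa = wham_1d(a, n_bins=60, grid_range_nm=grid)
        pb = wham_1d(b, n_bins=60, grid_range_nm=grid)
        ok = np.isfinite(pa.w_kj_mol) & np.isfinite(pb.w_kj_mol)
        assert np.allclose(pa.w_kj_mol[ok], pb.w_kj_mol[ok], atol=1e-6)

    def test_disjoint_windows_rejected(self):
        rng = np.random.default_rng(1)
        w1 = UmbrellaWindow(0.0, 1000.0, rng.normal(0.0, 0.05, 500))
        w2 = UmbrellaWindow(5.0, 1000.0, rng.normal(5.0, 0.05, 500))
        with pytest.raises(ValueError, match="no occupied bin"):
            wham_1d([w1, w2])


class TestBayesianBootstrap:
    @pytest.fixture(scope="class")
    def small_windows(self):
        centers = [0.8 + 0.05 * i for i in range(15)]
        return sample_biased_synthetic(double_well, centers, n_per_window=1500, seed=8)

    def test_single_replicate_gives_zero_sd(self, small_windows):
        sd = bayesian_bootstrap_pmf(small_windows, n_boot=1, seed=0)
        assert np.allclose(sd[np.isfinite(sd)], 0.0)

    def test_identical_seed_identical_sds(self, small_windows):
        a = bayesian_bootstrap_pmf(small_windows, n_boot=10, seed=4)
        b = bayesian_bootstrap_pmf(small_windows, n_boot=10, seed=4)
        assert np.array_equal(a[np.isfinite(a)], b[np.isfinite(b)])

    def test_sd_shrinks_with_sample_size(self):
        """Quadrupling the per-window sample roughly halves the error bars."""
        centers = [0.8 + 0.05 * i for i in range(15)]
        sds = []
        for n in (800, 3200):
            wins = sample_biased_synthetic(double_well, centers, n_per_window=n, seed=10)
            sd = bayesian_bootstrap_pmf(wins, n_boot=40, seed=1)
            sds.append(np.nanmedian(sd))
        ratio = sds[1] / sds[0]
        assert 0.35 <= ratio <= 0.65


class TestEstimateKd:
    def test_square_well_matches_analytic_integral(self):
        xi = np.linspace(0.0, 2.0, 401)
        w = np.where(xi <= 0.5, 0.0, 40.0)
        prof = PMFProfile(xi_nm=xi, w_kj_mol=w, temperature_K=323.0)
        kd = estimate_kd(prof, bound_range_nm=(0.0, 0.5))
        kT = KB_KJ_PER_MOL_K * 323.0
        analytic = STANDARD_STATE_VOLUME_NM3 / (0.5 * np.exp(40.0 / kT))
        assert kd.kd_mol_per_l == pytest.approx(analytic, rel=0.01)
        assert "standard-state" in kd.convention

    def test_flat_profile_gives_pure_standard_state_ratio(self):
        xi = np.linspace(0.0, 1.0, 101)
        prof = PMFProfile(xi_nm=xi, w_kj_mol=np.zeros_like(xi), temperature_K=323.0)
        kd = estimate_kd(prof, bound_range_nm=(0.0, 1.0))
        assert kd.kd_mol_per_l == pytest.approx(STANDARD_STATE_VOLUME_NM3 / 1.0)

    def test_deeper_well_gives_smaller_kd(self):
        xi = np.linspace(0.0, 2.0, 401)
        kds = []
        for depth in (40.0, 50.0):
            w = np.where(xi <= 0.5, 0.0, depth)
            prof = PMFProfile(xi_nm=xi, w_kj_mol=w, temperature_K=323.0)
            kds.append(estimate_kd(prof, bound_range_nm=(0.0, 0.5)).kd_mol_per_l)
        assert kds[1] < kds[0]

    @settings(max_examples=40, deadline=None)
    @given(
        depth=st.floats(5.0, 60.0),
        extra=st.floats(1.0, 25.0),
        width=st.floats(0.1, 0.8),
    )
    def test_kd_strictly_decreasing_in_well_depth(self, depth, extra, width):
        xi = np.linspace(0.0, 2.0, 201)
        shallow = np.where(xi <= width, 0.0, depth)
        deep = np.where(xi <= width, 0.0, depth + extra)
        ks = estimate_kd(
            PMFProfile(xi, shallow, 323.0), bound_range_nm=(0.0, width)
        ).kd_mol_per_l
        kd = estimate_kd(
            PMFProfile(xi, deep, 323.0), bound_range_nm=(0.0, width)
        ).kd_mol_per_l
        assert kd < ks

    def test_unsampled_bound_region_rejected(self):
        xi = np.linspace(0.0, 1.0, 11)
        prof = PMFProfile(xi, np.zeros_like(xi), 323.0)
        with pytest.raises(ValueError):
            estimate_kd(prof, bound_range_nm=(5.0, 6.0))
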