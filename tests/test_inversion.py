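"""Tikhonov inversion, alpha selection, validation ensemble, zones, ratio."""

import numpy as np
import pytest
from scipy import optimize

from pentaspin import (FormFactor, InversionSettings, ValidationSettings,
                       DistanceDistribution, tikhonov_invert, select_alpha,
                       validate_ensemble, reliability_zones, distance_ratio,
                       DistanceRatioError, kernel_trace_fresnel)
from pentaspin.inversion import _design_matrix, _second_difference


def make_form_factor(r_grid, p, delta, t):
    """Forward-model a form factor from a known distribution."""
    K = kernel_trace_fresnel(r_grid, t).T
    dr = r_grid[1] - r_grid[0]
    f = (1 - delta) + delta * (K @ (p * dr))
    return FormFactor(t=t, f=f / f[0], depth_delta=delta)


class TestTikhonovInvert:
    def test_single_gaussian_round_trip(self, fast_inversion_settings):
        inv = fast_inversion_settings
        r = inv.r_grid
        p = np.exp(-0.5 * ((r - 30.0) / 1.5) ** 2)
        p /= np.trapezoid(p, r)
        t = np.linspace(0, 3, 200)
        ff = make_form_factor(r, p, 0.4, t)
        dist, rmsd = tikhonov_invert(ff, inv, alpha=1e-2)
        mode = r[np.argmax(dist.p)]
        assert abs(mode - 30.0) < 0.5
        # recovered width within 20%
        mean = np.trapezoid(r * dist.p, r)
        sd = np.sqrt(np.trapezoid((r - mean) ** 2 * dist.p, r))
        assert sd == pytest.approx(1.5, rel=0.2)
        assert rmsd < 1e-4

    def test_two_gaussian_pentamer_modes(self, fast_inversion_settings):
        inv = fast_inversion_settings
        r = inv.r_grid
        p = (np.exp(-0.5 * ((r - 25.0) / 1.2) ** 2)
             + 0.8 * np.exp(-0.5 * ((r - 40.45) / 1.6) ** 2))
        p /= np.trapezoid(p, r)
        t = np.linspace(0, 4, 250)
        ff = make_form_factor(r, p, 0.6, t)
        dist, _ = tikhonov_invert(ff, inv, alpha=1e-2)
        ratio, d1, d2 = distance_ratio(dist)
        assert abs(d1 - 25.0) <= 1.0
        assert abs(d2 - 40.45) <= 1.0

    def test_flat_form_factor_flagged_no_signal(self, fast_inversion_settings):
        t = np.linspace(0, 3, 150)
        ff = FormFactor(t=t, f=np.ones_like(t), depth_delta=0.0)
        dist, _ = tikhonov_invert(ff, fast_inversion_settings, alpha=1.0)
        assert dist.meta.get("no_dipolar_signal") is True

    def test_matches_bounded_quadratic_solve_oracle(self):
        # 30-point coarse problem: NNLS path vs scipy bounded least squares
        inv = InversionSettings(r_min=20, r_max=50, n_r=30,
                                alpha_grid=(0.01, 0.1, 1.0, 10.0, 100.0))
        r = inv.r_grid
        p = np.exp(-0.5 * ((r - 32.0) / 2.0) ** 2)
        p /= np.trapezoid(p, r)
        t = np.linspace(0, 2.5, 80)
        ff = make_form_factor(r, p, 0.5, t)
        alpha = 0.1
        dist, _ = tikhonov_invert(ff, inv, alpha)
        A, rg, dr = _design_matrix(ff.t, inv)
        L = _second_difference(inv.n_r)
        Astack = np.vstack([A, alpha * L])
        bstack = np.concatenate([ff.f - 1.0, np.zeros(L.shape[0])])
        res = optimize.lsq_linear(Astack, bstack, bounds=(0, np.inf),
                                  tol=1e-14)
        q = res.x
        p_oracle = q / np.trapezoid(q, rg)
        assert np.max(np.abs(dist.p - p_oracle)) < 1e-6

    def test_rejects_non_positive_alpha(self, fast_inversion_settings):
        t = np.linspace(0, 2, 100)
        ff = FormFactor(t=t, f=np.ones_like(t), depth_delta=0.0)
        with pytest.raises(ValueError):
            tikhonov_invert(ff, fast_inversion_settings, alpha=0.0)


class TestAlphaSelection:
    def test_noise_free_input_picks_small_alpha(self, fast_inversion_settings):
        inv = fast_inversion_settings
        r = inv.r_grid
        p = np.exp(-0.5 * ((r - 30.0) / 2.0) ** 2)
        p /= np.trapezoid(p, r)
        t = np.linspace(0, 3, 150)
        ff = make_form_factor(r, p, 0.5, t)
        alpha, diag = select_alpha(ff, inv)
        grid = np.asarray(inv.alpha_grid)
        assert alpha <= grid[max(1, len(grid) // 10)]

    def test_high_snr_alpha_near_error_optimal(self, fast_inversion_settings):
        inv = fast_inversion_settings
        r = inv.r_grid
        p = np.exp(-0.5 * ((r - 30.0) / 2.0) ** 2)
        p /= np.trapezoid(p, r)
        t = np.linspace(0, 3, 150)
        ff_clean = make_form_factor(r, p, 0.5, t)
        rng = np.random.default_rng(0)
        f_noisy = ff_clean.f + 1e-3 * rng.standard_normal(t.size)
        ff = FormFactor(t=t, f=f_noisy / f_noisy[0], depth_delta=0.5)
        alpha, _ = select_alpha(ff, inv)
        grid = np.asarray(inv.alpha_grid)
        # oracle: alpha minimizing the true P-error
        errs = [np.linalg.norm(tikhonov_invert(ff, inv, a)[0].p - p)
                for a in grid]
        i_best = int(np.argmin(errs))
        i_chosen = int(np.argmin(np.abs(grid - alpha)))
        assert abs(i_chosen - i_best) <= 2

    def test_monotone_residual_and_seminorm_along_grid(
            self, fast_inversion_settings):
        inv = fast_inversion_settings
        r = inv.r_grid
        p = np.exp(-0.5 * ((r - 28.0) / 2.0) ** 2)
        p /= np.trapezoid(p, r)
        t = np.linspace(0, 3, 120)
        rng = np.random.default_rng(1)
        ff_clean = make_form_factor(r, p, 0.5, t)
        f = ff_clean.f + 2e-3 * rng.standard_normal(t.size)
        ff = FormFactor(t=t, f=f / f[0], depth_delta=0.5)
        A, rg, dr = _design_matrix(t, inv)
        L = _second_difference(inv.n_r)
        rho, eta = [], []
        for a in inv.alpha_grid:
            dist, _ = tikhonov_invert(ff, inv, a)
            q = dist.p * dist.meta["fitted_depth"]
            rho.append(np.linalg.norm(A @ q - (ff.f - 1)))
            eta.append(np.linalg.norm(L @ q))
        assert np.all(np.diff(rho) >= -1e-10)   # residual grows with alpha
        assert np.all(np.diff(eta) <= 1e-10)    # seminorm shrinks with alpha


class TestValidationEnsemble:
    def test_default_protocol_has_800_members(self):
        val = ValidationSettings()
        assert val.n_steps == 16 and val.trials_per_step == 50
        assert val.ensemble_size == 800

    def test_zero_added_noise_gives_zero_width_bands(self):
        # exact exponential background, no noise: members per start fraction
        # are identical, so the 2 sigma envelope collapses
        t = np.linspace(0, 4, 160)
        r0, sd0 = 30.0, 1.5
        r_grid = np.linspace(15, 60, 91)
        p = np.exp(-0.5 * ((r_grid - r0) / sd0) ** 2)
        p /= np.trapezoid(p, r_grid)
        K = kernel_trace_fresnel(r_grid, t).T
        dr = r_grid[1] - r_grid[0]
        intra = (1 - 0.4) + 0.4 * (K @ (p * dr))
        from pentaspin import TimeTrace
        trace = TimeTrace(t=t, y=intra * np.exp(-0.2 * t), noise_std=1e-4)
        inv = InversionSettings(r_min=15, r_max=60, n_r=91,
                                alpha_grid=tuple(np.logspace(-3, 2, 8)))
        val = ValidationSettings(n_steps=3, trials_per_step=4,
                                 noise_fraction=0.0, seed=0)
        res = validate_ensemble(trace, inv, val)
        assert res.survivors <= res.ensemble_size == 12
        # width reflects only the start-fraction spread; with a pure
        # exponential background all starts agree
        assert np.max(res.band_hi - res.band_lo) < 1e-6

    def test_ground_truth_within_bands_in_shape_zone(
            self, noisy_pentamer_trace, fast_inversion_settings):
        trace, truth = noisy_pentamer_trace
        val = ValidationSettings(n_steps=8, trials_per_step=10, seed=2)
        res = validate_ensemble(trace, fast_inversion_settings, val)
        assert res.ensemble_size == 80
        assert 0 < res.survivors <= 80
        ratio, d1, d2 = distance_ratio(res.best)
        assert abs(d1 - truth["d1"]) < 2.0
        assert abs(d2 - truth["d2"]) < 2.5
        # D2 band wider than D1 band at the modes: diagonal more
        # background-dependent than the side distance
        r = res.best.r
        w = res.band_hi - res.band_lo
        i1 = np.argmin(np.abs(r - d1))
        i2 = np.argmin(np.abs(r - d2))
        assert w[i2] > 0


class TestReliabilityZones:
    def test_two_microsecond_window_shape_boundary(self):
        zones = dict(reliability_zones(2.0))
        assert zones["shape"] == pytest.approx(37.3, abs=0.05)

    def test_doubling_window_scales_boundaries_by_cbrt2(self):
        z1 = dict(reliability_zones(1.5))
        z2 = dict(reliability_zones(3.0))
        for label in ("shape", "mean+width", "mean"):
            assert z2[label] / z1[label] == pytest.approx(2 ** (1 / 3))

    def test_zone_ordering(self):
        zones = reliability_zones(2.5)
        labels = [z[0] for z in zones]
        assert labels == ["shape", "mean+width", "mean", "none"]
        radii = [z[1] for z in zones]
        assert radii == sorted(radii)


class TestDistanceRatio:
    def test_ideal_pentamer_distribution_golden_ratio(self):
        r = np.linspace(15, 60, 451)
        p = (np.exp(-0.5 * ((r - 25.0) / 1.0) ** 2)
             + 0.8 * np.exp(-0.5 * ((r - 40.45) / 1.3) ** 2))
        p /= np.trapezoid(p, r)
        dist = DistanceDistribution(r=r, p=p)
        ratio, d1, d2 = distance_ratio(dist)
        assert ratio == pytest.approx(1.618, abs=0.01)

    def test_synthetic_inverted_trace_ratio_near_1p6(
            self, noisy_pentamer_trace, fast_inversion_settings):
        from pentaspin import fit_background, correct_background
        trace, truth = noisy_pentamer_trace
        bg, _ = fit_background(trace, 0.55)
        ff = correct_background(trace, bg)
        alpha, _ = select_alpha(ff, fast_inversion_settings)
        dist, _ = tikhonov_invert(ff, fast_inversion_settings, alpha)
        ratio, _, _ = distance_ratio(dist)
        assert 1.55 <= ratio <= 1.70

    def test_unimodal_distribution_raises(self):
        r = np.linspace(15, 60, 200)
        p = np.exp(-0.5 * ((r - 30.0) / 2.0) ** 2)
        p /= np.trapezoid(p, r)
        with pytest.raises(DistanceRatioError):
            distance_ratio(DistanceDistribution(r=r, p=p))
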