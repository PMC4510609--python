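"""Per-pixel variational fitting: energy, semi-explicit scheme,
initialization protocol, whole-image fits and the Hessian closed forms."""

import numpy as np
import pytest

from rhodomap import (AFMovie, FitConfig, PixelModelParams, energy,
                      energy_hessian, fit_image, fit_pixel, forward_af,
                      initialize, update_step)
from rhodomap.fit import (BleachModelFitter, InitValues, block_average,
                          fit_curves, quad_weights)
from rhodomap.model import Geometry
from tests.conftest import small_spec

TIMES = np.arange(480) / 8.0


def model_curve(alpha, beta, gamma, times=TIMES):
    return forward_af(times, PixelModelParams(alpha, beta, gamma))


def grid_search_energy(f, times, b, p_range, c_range, n=200):
    """Independent brute-force minimizer of E over a (p, c) grid."""
    p_grid = np.linspace(*p_range, n)
    c_grid = np.linspace(*c_range, n)
    w = quad_weights(times)
    lnf = np.log(f)
    ebt = np.exp(-b * times)
    # E(p, c) = sum (lnf - p + c e^{-bt})^2 w over the grid
    r = (lnf[None, None, :] - p_grid[:, None, None]
         + c_grid[None, :, None] * ebt[None, None, :])
    E = np.einsum("ijk,k->ij", r * r, w)
    i, j = np.unravel_index(np.argmin(E), E.shape)
    return p_grid[i], c_grid[j], p_grid[1] - p_grid[0], c_grid[1] - c_grid[0]


class TestEnergy:
    def test_model_consistent_curve_is_zero(self):
        p, b, c = np.log(100.0), 0.32, 0.7
        f = np.exp(p - c * np.exp(-b * TIMES))
        assert energy(f, p, b, c, TIMES) < 1e-20

    def test_hand_evaluated_two_sample_sum(self):
        f = np.array([np.e, np.e ** 2])
        t = np.array([0.0, 1.0])
        assert energy(f, 0.0, 1.0, 0.0, t) == pytest.approx(5.0, rel=1e-12)

    def test_log_shift_identity(self):
        rng = np.random.default_rng(0)
        f = np.abs(rng.normal(50, 5, size=64)) + 1.0
        t = np.linspace(0, 60, 64)
        delta = 0.37
        e1 = energy(f, 1.2, 0.3, 0.5, t)
        e2 = energy(f * np.exp(delta), 1.2 + delta, 0.3, 0.5, t)
        assert e1 == pytest.approx(e2, rel=1e-10)

    def test_nonpositive_sample_rejected(self):
        with pytest.raises(ValueError, match="mask"):
            energy(np.array([1.0, 0.0, 2.0]), 0.0, 0.3, 0.0,
                   np.array([0.0, 1.0, 2.0]))


class TestUpdateStep:
    def test_fixed_point_at_exact_minimizer(self):
        p, b, c = np.log(100.0), 0.32, 0.7
        f = np.exp(p - c * np.exp(-b * TIMES))
        cfg = FitConfig(fix_b=False)
        p2, b2, c2 = update_step(p, b, c, f, TIMES, cfg)
        assert abs(p2 - p) < 1e-12
        assert abs(b2 - b) < 1e-12
        assert abs(c2 - c) < 1e-12

    def test_one_step_matches_hand_evaluated_closed_forms(self):
        """Independent evaluation of the two implicit closed forms."""
        f = np.array([30.0, 50.0, 70.0])
        t = np.array([0.0, 1.0, 2.0])
        b = 0.5
        cfg = FitConfig(tau_p=0.1, tau_c=0.1, fix_b=True)
        p2, b2, c2 = update_step(0.0, b, 0.0, f, t, cfg)
        w = np.array([1.0, 1.0, 1.0])
        lnf, ebt = np.log(f), np.exp(-b * t)
        exp_p = (0.0 + 2 * 0.1 * np.sum((lnf + 0.0) * w)) / (1 + 2 * 0.1 * 3.0)
        exp_c = (0.0 - 2 * 0.1 * np.sum(lnf * ebt * w)) \
            / (1 + 2 * 0.1 * np.sum(ebt ** 2 * w))
        assert p2 == pytest.approx(exp_p, rel=1e-14)
        assert b2 == b
        assert c2 == pytest.approx(exp_c, rel=1e-14)

    def test_energy_decreases_on_random_curves(self):
        """One sweep never increases E for sufficiently small steps
        (100 draws; the explicit b-update dictates the small tau_b)."""
        t = np.linspace(0, 20, 40)
        cfg = FitConfig(tau_c=0.05, tau_b=1e-4, fix_b=False)
        for seed in range(100):
            rng = np.random.default_rng(seed)
            f = model_curve(rng.uniform(20, 200), rng.uniform(0.1, 0.5),
                            rng.uniform(0.1, 1.5), t)
            f = f * np.exp(rng.normal(0, 0.02, size=t.size))
            p0 = np.log(f.mean()) + rng.normal(0, 0.3)
            b0 = rng.uniform(0.1, 0.5)
            c0 = rng.uniform(0.0, 1.0)
            p1, b1, c1 = update_step(p0, b0, c0, f, t, cfg)
            assert (energy(f, p1, b1, c1, t)
                    <= energy(f, p0, b0, c0, t) + 1e-12)

    def test_negative_rate_rejected(self):
        with pytest.raises(FloatingPointError):
            update_step(0.0, -0.1, 0.0, np.array([1.0, 2.0, 3.0]),
                        np.array([0.0, 1.0, 2.0]), FitConfig())


class TestFitPixel:
    def test_constant_curve_gives_zero_density(self):
        f = np.full(TIMES.size, 80.0)
        a, b, c, n, conv = fit_pixel(f, TIMES, (np.log(80.0), 0.32, 0.5),
                                     FitConfig())
        assert conv
        assert abs(c) < 1e-6
        assert a == pytest.approx(80.0, rel=1e-6)

    def test_noiseless_recovery_with_fixed_rate(self):
        f = model_curve(100.0, 0.04, 0.7)
        a, b, c, n, conv = fit_pixel(f, TIMES, (np.log(60.0), 0.04, 0.1),
                                     FitConfig())
        assert conv
        assert a == pytest.approx(100.0, rel=1e-3)
        assert c == pytest.approx(0.7, rel=1e-3)

    def test_noisy_fit_matches_grid_search_oracle(self):
        rng = np.random.default_rng(11)
        f = model_curve(100.0, 0.32, 0.7) + rng.normal(0, 2.0, TIMES.size)
        assert np.all(f > 0)
        b = 0.32
        a, _, c, n, conv = fit_pixel(f, TIMES, (np.log(90.0), b, 0.4),
                                     FitConfig())
        p_star, c_star, dp, dc = grid_search_energy(
            f, TIMES, b, (np.log(a) - 0.05, np.log(a) + 0.05),
            (c - 0.05, c + 0.05))
        assert abs(np.log(a) - p_star) <= dp
        assert abs(c - c_star) <= dc

    def test_global_minimum_on_random_instances(self):
        """Fixed-b fits agree with brute-force search (unique minimum)."""
        t = np.linspace(0, 30, 60)
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            alpha = rng.uniform(30, 150)
            gamma = rng.uniform(0.1, 1.2)
            b = rng.uniform(0.1, 0.5)
            f = model_curve(alpha, b, gamma, t) \
                * np.exp(rng.normal(0, 0.03, size=t.size))
            a, _, c, n, conv = fit_pixel(
                f, t, (np.log(alpha) + 0.2, b, 0.0), FitConfig())
            assert conv
            p_star, c_star, dp, dc = grid_search_energy(
                f, t, b, (np.log(a) - 0.1, np.log(a) + 0.1),
                (c - 0.1, c + 0.1))
            assert abs(np.log(a) - p_star) <= dp
            assert abs(c - c_star) <= dc

    def test_scale_equivariance(self):
        f = model_curve(100.0, 0.32, 0.7)
        cfg = FitConfig()
        a1, _, c1, _, _ = fit_pixel(f, TIMES, (np.log(90.0), 0.32, 0.4), cfg)
        s = 3.5
        a2, _, c2, _, _ = fit_pixel(s * f, TIMES,
                                    (np.log(s * 90.0), 0.32, 0.4), cfg)
        assert a2 == pytest.approx(s * a1, rel=1e-6)
        assert c2 == pytest.approx(c1, abs=1e-6)

    def test_three_parameter_recovery(self):
        f = model_curve(100.0, 0.32, 0.7)
        cfg = FitConfig(fix_b=False, max_iters=20000)
        a, b, c, n, conv = fit_pixel(f, TIMES, (np.log(80.0), 0.25, 0.3), cfg)
        assert conv
        assert a == pytest.approx(100.0, rel=1e-3)
        assert b == pytest.approx(0.32, rel=1e-2)
        assert c == pytest.approx(0.7, rel=1e-2)


class TestBlockAverage:
    def _movie(self, frames):
        geom = Geometry(30.0, (frames.shape[1] / 2, frames.shape[2] / 2), 2.0)
        return AFMovie(frames, np.arange(frames.shape[0], dtype=float),
                       geometry=geom)

    def test_constant_frame_unchanged(self):
        movie = self._movie(np.full((3, 32, 32), 5.0))
        out = block_average(movie, 8)
        assert np.allclose(out.frames, 5.0)

    def test_impulse_response_of_mean_filter(self):
        frames = np.zeros((3, 32, 32))
        frames[:, 16, 16] = 64.0
        out = block_average(self._movie(frames), 8)
        covered = out.frames[0] > 0
        assert covered.sum() == 64
        assert np.allclose(out.frames[0][covered], 1.0)

    def test_linear_ramp_unchanged_in_interior(self):
        ramp = np.tile(np.arange(32, dtype=float), (32, 1))
        # odd window: symmetric, exact invariance on a linear function
        out = block_average(self._movie(np.stack([ramp] * 3)), 7)
        assert np.allclose(out.frames[0][8:-8, 8:-8], ramp[8:-8, 8:-8])
        # even window: centered on a half-pixel, shifts a ramp by 1/2
        out8 = block_average(self._movie(np.stack([ramp] * 3)), 8)
        assert np.allclose(out8.frames[0][8:-8, 8:-8],
                           ramp[8:-8, 8:-8] - 0.5)

    def test_window_larger_than_image_errors(self):
        with pytest.raises(ValueError):
            block_average(self._movie(np.ones((3, 8, 8))), 9)


class TestInitialize:
    def test_rate_recovered_from_histogram_mode(self, clean_small_phantom):
        spec, movie, truth = clean_small_phantom
        init = initialize(movie, None, None, FitConfig())
        counts, edges = init.b_histogram
        bin_width = edges[1] - edges[0]
        # noiseless fits cluster so tightly that the Freedman-Diaconis
        # bins shrink below the b-mode's own convergence tolerance; the
        # mode is then still accurate to a fraction of a percent
        assert abs(init.b0 - truth.beta) <= max(bin_width,
                                                1e-3 * truth.beta)

    def test_constant_p0_without_mp_map(self, clean_small_phantom):
        _, movie, _ = clean_small_phantom
        init = initialize(movie, None, None, FitConfig())
        assert np.ptp(init.p0_field) == 0.0

    def test_initial_energy_beats_naive_start(self, clean_small_phantom):
        spec, movie, _ = clean_small_phantom
        init = initialize(movie, None, None, FitConfig())
        r = movie.geometry.radius_map(movie.shape)
        mask = (r >= 5.0) & (r <= 8.0)
        curve = movie.frames[:, mask].mean(axis=1)
        p_a, b_a, c_a = init.annulus_fit
        assert (energy(curve, p_a, b_a, c_a, movie.times)
                < energy(curve, 0.0, 0.01, 0.0, movie.times))

    def test_empty_annulus_errors(self, clean_small_phantom):
        _, movie, _ = clean_small_phantom
        with pytest.raises(ValueError, match="annulus"):
            initialize(movie, None, None, FitConfig(),
                       annulus_deg=(500.0, 501.0))


class TestFitImage:
    def test_noiseless_phantom_recovery(self):
        """Median relative density error below 0.5% away from the fovea."""
        spec = small_spec(noise_sigma=0.0, n_vessels=0, dtype="float64")
        from rhodomap import generate_movie
        movie, truth = generate_movie(spec)
        init = initialize(movie, None, None, FitConfig())
        fit = fit_image(movie, init, FitConfig())
        r = movie.geometry.radius_map(movie.shape)
        sel = fit.converged & (truth.gamma_map > 0.2)
        rel = np.abs(fit.c_hat - truth.gamma_map)[sel] / truth.gamma_map[sel]
        assert np.median(rel) < 0.005

    def test_constant_movie_gives_zero_density(self):
        geom = Geometry(24.0, (24, 24), 2.0)
        movie = AFMovie(np.full((40, 48, 48), 60.0), np.arange(40) / 8.0,
                        geometry=geom)
        init = InitValues(p0_field=np.full((48, 48), np.log(60.0)), b0=0.3,
                          c0=0.2)
        fit = fit_image(movie, init, FitConfig())
        assert np.all(np.abs(fit.c_hat) < 1e-5)

    def test_bit_identical_reruns(self, clean_small_phantom):
        _, movie, _ = clean_small_phantom
        cfg = FitConfig()
        init = initialize(movie, None, None, cfg)
        f1 = fit_image(movie, init, cfg)
        f2 = fit_image(movie, init, cfg)
        assert np.array_equal(f1.c_hat, f2.c_hat)
        assert np.array_equal(f1.a_hat, f2.a_hat)
        assert np.array_equal(f1.n_iters, f2.n_iters)

    def test_nonpositive_pixels_masked_not_fatal(self):
        geom = Geometry(24.0, (24, 24), 2.0)
        frames = np.tile(model_curve(80.0, 0.32, 0.5, np.arange(40) / 8.0)
                         [:, None, None], (1, 48, 48))
        frames[:, 10, 10] = 0.0
        movie = AFMovie(frames, np.arange(40) / 8.0, geometry=geom)
        init = InitValues(p0_field=np.full((48, 48), np.log(80.0)), b0=0.32,
                          c0=0.5)
        fit = fit_image(movie, init, FitConfig(block_size=1))
        assert fit.masked[10, 10]
        assert not fit.converged[10, 10]
        assert fit.converged[0, 0]


class TestEnergyHessian:
    def test_degenerate_at_zero_rate(self):
        H = energy_hessian(0.0, TIMES)
        assert abs(np.linalg.det(H)) < 1e-9

    def test_positive_definite_for_positive_rate(self):
        H = energy_hessian(0.04, np.linspace(0, 60, 480))
        assert H[0, 0] > 0
        assert np.linalg.det(H) > 0

    def test_matches_finite_differences_of_energy(self):
        """Closed forms vs central second differences of E."""
        t = np.linspace(0, 30, 120)
        rng = np.random.default_rng(5)
        f = np.abs(rng.normal(60, 5, size=t.size)) + 10.0
        b, p, c, h = 0.2, 3.9, 0.4, 1e-4

        def E(pp, cc):
            return energy(f, pp, b, cc, t)

        dpp = (E(p + h, c) - 2 * E(p, c) + E(p - h, c)) / h ** 2
        dcc = (E(p, c + h) - 2 * E(p, c) + E(p, c - h)) / h ** 2
        dpc = (E(p + h, c + h) - E(p + h, c - h)
               - E(p - h, c + h) + E(p - h, c - h)) / (4 * h ** 2)
        H = energy_hessian(b, t)
        assert H[0, 0] == pytest.approx(dpp, abs=1e-5 * max(1, abs(dpp)))
        assert H[1, 1] == pytest.approx(dcc, abs=1e-5 * max(1, abs(dcc)))
        assert H[0, 1] == pytest.approx(dpc, abs=1e-5 * max(1, abs(dpc)))
        assert H[0, 1] < 0  # cross partial is negative


def test_estimator_surface(clean_small_phantom):
    """BleachModelFitter exposes sklearn params and fitted attributes."""
    from sklearn.base import clone

    _, movie, truth = clean_small_phantom
    est = clone(BleachModelFitter(max_subsample=256))
    est.fit(movie)
    assert est.b0_ == pytest.approx(truth.beta, rel=0.05)
    assert est.gamma_map_.shape == movie.shape
    assert est.get_params()["block_size"] == 8
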