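"""DEER: dipolar kernel physics, background correction, Tikhonov
inversion, regularization selection and distribution statistics."""

import numpy as np
import pytest
from scipy.integrate import quad

from dimerlab import deer


@pytest.fixture(scope="module")
def r_grid():
    return deer.default_r_grid()


@pytest.fixture(scope="module")
def gaussian_truth(r_grid):
    return deer.DistanceDistribution.gaussian(r_grid, 5.0, 0.3)


@pytest.fixture(scope="module")
def background():
    return deer.BackgroundModel(k=0.1, modulation_depth=0.3)


# --------------------------------------------------------------------- kernel

class TestKernel:
    def test_unit_value_at_time_zero(self, r_grid):
        K = deer.dipolar_kernel(np.array([0.0]), r_grid)
        np.testing.assert_allclose(K[0], 1.0, atol=1e-12)

    def test_dipolar_frequency_closed_form(self):
        assert deer.dipolar_frequency(1.0) == pytest.approx(52.04)
        assert deer.dipolar_frequency(2.0) == pytest.approx(6.505)

    @pytest.mark.parametrize("r,t", [(2.0, 0.5), (3.5, 1.0), (5.0, 2.0),
                                     (7.0, 4.0)])
    def test_matches_adaptive_quadrature(self, r, t):
        omega = 2 * np.pi * deer.DIPOLAR_CONSTANT_MHZ_NM3 / r ** 3
        expect, _ = quad(lambda x: np.cos((1 - 3 * x ** 2) * omega * t),
                         0, 1, limit=400)
        got = deer.dipolar_kernel(np.array([t]), np.array([r]))[0, 0]
        assert got == pytest.approx(expect, abs=1e-6)

    def test_even_in_time_and_bounded(self, r_grid):
        t = np.linspace(0.0, 6.0, 80)
        K_pos = deer.dipolar_kernel(t, r_grid)
        K_neg = deer.dipolar_kernel(-t[::-1], r_grid)
        np.testing.assert_allclose(K_neg[::-1], K_pos, atol=1e-10)
        assert K_pos.min() >= -0.5 - 1e-9
        assert K_pos.max() <= 1.0 + 1e-12

    def test_nonpositive_distance_rejected(self):
        with pytest.raises(ValueError):
            deer.dipolar_kernel(np.array([0.1]), np.array([0.0]))


# ----------------------------------------------------------------- simulation

class TestSimulate:
    def test_zero_modulation_is_pure_background(self, gaussian_truth):
        bg = deer.BackgroundModel(k=0.25, modulation_depth=0.0)
        tr = deer.simulate_trace(gaussian_truth, bg)
        np.testing.assert_allclose(tr.V, np.exp(-0.25 * tr.t), rtol=1e-12)

    def test_delta_distribution_closed_form(self, r_grid):
        r0 = 4.0
        P = np.zeros_like(r_grid)
        P[np.argmin(np.abs(r_grid - r0))] = 1.0
        delta = deer.DistanceDistribution.from_values(r_grid, P)
        lam = 0.4
        tr = deer.simulate_trace(delta,
                                 deer.BackgroundModel(k=0.0,
                                                      modulation_depth=lam))
        r_at = r_grid[np.argmin(np.abs(r_grid - r0))]
        K = deer.dipolar_kernel(tr.t, np.array([r_at]))[:, 0]
        np.testing.assert_allclose(tr.V, 1 - lam + lam * K, rtol=1e-9)

    def test_acquisition_grid_matches_settings(self):
        t = deer.acquisition_time_grid({"tau2_us": 8.0, "dt_ns": 16.0})
        assert t[0] == 0.0
        assert t[1] - t[0] == pytest.approx(0.016)
        assert t[-1] <= 8.0 - 2 * 0.056 + 1e-9


# ----------------------------------------------------------------- background

class TestBackground:
    def test_pure_background_gives_unit_evolution(self):
        t = np.arange(0, 6, 0.016)
        tr = deer.DeerTrace(t=t, V=np.exp(-0.2 * t))
        with pytest.warns(UserWarning, match="shallow modulation"):
            F, bg = deer.background_correct(tr)
        np.testing.assert_allclose(F, 1.0, atol=1e-9)
        assert bg.modulation_depth == pytest.approx(0.0, abs=1e-9)
        assert bg.k == pytest.approx(0.2, abs=1e-9)

    def test_known_modulation_depth_recovered(self, gaussian_truth,
                                              background):
        lams = []
        for seed in range(10):
            tr = deer.simulate_trace(gaussian_truth, background,
                                     noise_sd=1 / 50, rng_seed=seed,
                                     acquisition={"tau2_us": 8.0})
            _, bg = deer.background_correct(tr)
            lams.append(bg.modulation_depth)
        assert np.median(lams) == pytest.approx(0.3, abs=0.015)

    def test_shallow_modulation_warns_but_returns(self, gaussian_truth):
        bg_in = deer.BackgroundModel(k=0.1, modulation_depth=0.05)
        tr = deer.simulate_trace(gaussian_truth, bg_in, noise_sd=1e-4,
                                 rng_seed=1)
        with pytest.warns(UserWarning, match="shallow modulation"):
            F, bg = deer.background_correct(tr)
        assert len(F) == len(tr.t)

    def test_nondecaying_tail_clamped(self):
        t = np.arange(0, 6, 0.016)
        tr = deer.DeerTrace(t=t, V=np.exp(+0.05 * t) / np.exp(0.0))
        with pytest.warns(UserWarning, match="non-decaying"):
            _, bg = deer.background_correct(tr)
        assert bg.k == 0.0 and bg.clamped


# ------------------------------------------------------------------ inversion

class TestTikhonov:
    def test_noiseless_gaussian_mode_recovery(self, gaussian_truth, r_grid):
        tr = deer.simulate_trace(gaussian_truth,
                                 deer.BackgroundModel(k=0.0,
                                                      modulation_depth=1.0))
        res = deer.tikhonov_invert(tr.V, tr.t, r_grid, alpha=0.1)
        mode = r_grid[np.argmax(res.distribution.P)]
        assert mode == pytest.approx(5.0, abs=0.1)

    def test_constraints_always_hold(self, gaussian_truth, background,
                                     r_grid):
        tr = deer.simulate_trace(gaussian_truth, background, noise_sd=1 / 20,
                                 rng_seed=4)
        F, bg = deer.background_correct(tr)
        S = deer.form_factor_to_evolution(F, bg.modulation_depth)
        res = deer.tikhonov_invert(S, tr.t, r_grid, alpha=5.0)
        assert res.distribution.P.min() >= 0.0
        assert np.trapezoid(res.distribution.P, r_grid) == pytest.approx(
            1.0, abs=1e-6)

    def test_roundtrip_snr50_mode_within_0p1_nm(self, gaussian_truth,
                                                background):
        tr = deer.simulate_trace(gaussian_truth, background, noise_sd=1 / 50,
                                 rng_seed=21, acquisition={"tau2_us": 8.0})
        res = deer.invert_trace(tr)
        stats = deer.distribution_stats(res.distribution, min_mass=0.1)
        main = max(stats, key=lambda m: m["mass"])
        assert main["mode"] == pytest.approx(5.0, abs=0.1)

    def test_bimodal_broad5_sharp7_recovery(self, r_grid, background):
        truth = deer.DistanceDistribution.from_values(
            r_grid,
            0.6 * np.exp(-0.5 * ((r_grid - 5.0) / 0.8) ** 2) / 0.8
            + 0.4 * np.exp(-0.5 * ((r_grid - 7.0) / 0.15) ** 2) / 0.15)
        tr = deer.simulate_trace(truth, background, noise_sd=1 / 30,
                                 rng_seed=2, acquisition={"tau2_us": 8.0})
        res = deer.invert_trace(tr)
        stats = deer.distribution_stats(res.distribution, prominence=0.1,
                                        min_mass=0.1)
        modes = np.array([m["mode"] for m in stats])
        assert np.min(np.abs(modes - 5.0)) <= 0.2
        assert np.min(np.abs(modes - 7.0)) <= 0.2

    def test_deterministic_given_fixed_input(self, gaussian_truth,
                                             background, r_grid):
        tr = deer.simulate_trace(gaussian_truth, background, noise_sd=1 / 30,
                                 rng_seed=9)
        F, bg = deer.background_correct(tr)
        S = deer.form_factor_to_evolution(F, bg.modulation_depth)
        r1 = deer.tikhonov_invert(S, tr.t, r_grid, alpha=2.0)
        r2 = deer.tikhonov_invert(S, tr.t, r_grid, alpha=2.0)
        np.testing.assert_array_equal(r1.distribution.P, r2.distribution.P)

    def test_invalid_inputs_rejected(self, r_grid):
        with pytest.raises(ValueError):
            deer.tikhonov_invert(np.array([1.0]), np.array([0.0]), r_grid,
                                 alpha=0.0)
        with pytest.raises(ValueError):
            deer.tikhonov_invert(np.array([]), np.array([]),
                                 np.array([1.0, 2.0]), alpha=1.0)

    def test_long_distance_widths_broaden(self, r_grid, background):
        """Near the resolvable limit set by the time window, recovered
        distributions can only get wider, never sharper."""
        truth = deer.DistanceDistribution.gaussian(r_grid, 7.5, 0.2)
        tr = deer.simulate_trace(truth, background, noise_sd=1 / 30,
                                 rng_seed=3, acquisition={"tau2_us": 7.0})
        res = deer.invert_trace(tr)
        stats = deer.distribution_stats(res.distribution, min_mass=0.1)
        main = min(stats, key=lambda m: abs(m["mode"] - 7.5))
        assert main["sd"] >= 0.2


class TestChooseAlpha:
    @pytest.fixture(scope="class")
    def evolution(self, gaussian_truth, background):
        tr = deer.simulate_trace(gaussian_truth, background, noise_sd=1 / 50,
                                 rng_seed=7, acquisition={"tau2_us": 8.0})
        F, bg = deer.background_correct(tr)
        return deer.form_factor_to_evolution(F, bg.modulation_depth), tr.t

    def test_residual_monotone_in_alpha(self, evolution, r_grid):
        S, t = evolution
        _, diag = deer.choose_alpha(S, t, r_grid)
        assert np.all(np.diff(diag["residuals"]) >= -1e-9)

    def test_within_2x_of_oracle_optimal(self, evolution, r_grid,
                                         gaussian_truth):
        S, t = evolution
        grid = np.logspace(-3, 2, 21)
        errors = []
        for a in grid:
            res = deer.tikhonov_invert(S, t, r_grid, alpha=a)
            errors.append(np.trapezoid(
                np.abs(res.distribution.P - gaussian_truth.P), r_grid))
        errors = np.array(errors)
        chosen, _ = deer.choose_alpha(S, t, r_grid, alpha_grid=grid)
        err_chosen = errors[np.argmin(np.abs(grid - chosen))]
        assert err_chosen <= 2.0 * errors.min()

    def test_deterministic(self, evolution, r_grid):
        S, t = evolution
        a1, _ = deer.choose_alpha(S, t, r_grid)
        a2, _ = deer.choose_alpha(S, t, r_grid)
        assert a1 == a2

    def test_narrow_grid_rejected(self, evolution, r_grid):
        S, t = evolution
        with pytest.raises(ValueError, match="three decades"):
            deer.choose_alpha(S, t, r_grid, alpha_grid=np.logspace(0, 1, 5))


# ----------------------------------------------------------------- statistics

class TestDistributionStats:
    def test_single_gaussian_single_mode(self, r_grid):
        dist = deer.DistanceDistribution.gaussian(r_grid, 5.0, 0.4)
        stats = deer.distribution_stats(dist)
        assert len(stats) == 1
        spacing = r_grid[1] - r_grid[0]
        assert abs(stats[0]["mode"] - 5.0) <= spacing

    def test_mode_masses_sum_to_one(self, r_grid):
        dist = deer.DistanceDistribution.from_values(
            r_grid, np.exp(-0.5 * ((r_grid - 4.0) / 0.5) ** 2)
            + 0.7 * np.exp(-0.5 * ((r_grid - 7.0) / 0.3) ** 2))
        stats = deer.distribution_stats(dist)
        assert sum(m["mass"] for m in stats) == pytest.approx(1.0, abs=1e-6)

    def test_flat_distribution_has_no_modes(self, r_grid):
        dist = deer.DistanceDistribution.from_values(r_grid,
                                                     np.ones_like(r_grid))
        assert deer.distribution_stats(dist) == []

    def test_7p1_to_7p4_shift_recovered(self, r_grid, background):
        """Paired scenarios with a 0.3 nm shift of the long-distance mode
        (the hallmark of losing the closing contact) recover that shift
        within two grid spacings."""
        spacing = r_grid[1] - r_grid[0]
        modes = {}
        for label, mode in (("closed_like", 7.1), ("open_like", 7.4)):
            # sharp long-distance peaks, inverted with identical (fixed)
            # regularization so the paired comparison is like for like
            truth = deer.DistanceDistribution.gaussian(r_grid, mode, 0.15)
            tr = deer.simulate_trace(truth, background, noise_sd=1 / 50,
                                     rng_seed=13,
                                     acquisition={"tau2_us": 8.0})
            res = deer.invert_trace(tr, alpha=1.0)
            stats = deer.distribution_stats(res.distribution, min_mass=0.1)
            modes[label] = min(stats,
                               key=lambda m: abs(m["mode"] - mode))["mode"]
        shift = modes["open_like"] - modes["closed_like"]
        assert shift == pytest.approx(0.3, abs=2 * spacing)


# ------------------------------------------------------------------------ I/O

class TestIO:
    def test_trace_round_trip(self, tmp_path, gaussian_truth, background):
        tr = deer.simulate_trace(gaussian_truth, background)
        deer.write_trace(tr, tmp_path / "trace.dat")
        back = deer.read_trace(tmp_path / "trace.dat")
        np.testing.assert_allclose(back.t, tr.t, rtol=1e-6)
        np.testing.assert_allclose(back.V, tr.V, rtol=1e-5)

    def test_nanosecond_units(self, tmp_path):
        (tmp_path / "t.dat").write_text("0 1.0\n16 0.99\n32 0.98\n")
        tr = deer.read_trace(tmp_path / "t.dat", time_unit="ns")
        np.testing.assert_allclose(tr.t, [0.0, 0.016, 0.032])

    def test_distribution_round_trip(self, tmp_path, r_grid):
        dist = deer.DistanceDistribution.gaussian(r_grid, 5.0, 0.3)
        deer.write_distribution(dist, tmp_path / "p.dat")
        back = deer.read_distribution(tmp_path / "p.dat")
        np.testing.assert_allclose(back.P, dist.P, atol=1e-8)
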