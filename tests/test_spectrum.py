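"""Tests of the RBME likelihood, observed-jump weights and state-array
inference."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal

import chromodyn as cd
from chromodyn.spectrum import DiffusionGrid


def dense_rbme_loglik(jumps, d, sigma, dt):
    """Dense multivariate-normal oracle for the tridiagonal RBME density."""
    n = len(jumps)
    cov = (np.diag(np.full(n, 2 * d * dt + 2 * sigma ** 2))
           + np.diag(np.full(n - 1, -sigma ** 2), 1)
           + np.diag(np.full(n - 1, -sigma ** 2), -1))
    mvn = multivariate_normal(np.zeros(n), cov)
    return mvn.logpdf(jumps[:, 0]) + mvn.logpdf(jumps[:, 1])


class TestRBMELogLik:
    @pytest.mark.parametrize("n", [1, 2, 5, 20, 50])
    @pytest.mark.parametrize("d,sigma", [(1.0, 0.035), (0.02, 0.035),
                                         (10.0, 0.0), (0.0, 0.05)])
    def test_matches_dense_oracle(self, n, d, sigma):
        rng = np.random.default_rng(40 + n)
        jumps = rng.normal(0, 0.1, (n, 2))
        dt = 0.00748
        mine = cd.rbme_loglik(jumps, d, sigma, dt)
        oracle = dense_rbme_loglik(jumps, d, sigma, dt)
        assert abs(mine - oracle) <= 1e-8 * abs(oracle)

    def test_single_jump_no_noise_is_brownian_increment(self):
        """n=1, sigma=0: the density is a plain normal with variance
        2 D dt per axis."""
        d, dt = 1.5, 0.00748
        jump = np.array([[0.1, -0.05]])
        var = 2 * d * dt
        expected = sum(-0.5 * (np.log(2 * np.pi * var) + v ** 2 / var)
                       for v in jump[0])
        assert np.isclose(cd.rbme_loglik(jump, d, 0.0, dt), expected)

    def test_pure_noise_limit_zero_jump(self):
        """D=0 with a zero jump vector returns the multivariate-normal
        constant of the pure-noise covariance."""
        sigma, dt, n = 0.035, 0.00748, 4
        jumps = np.zeros((n, 4 // 2))
        cov = (np.diag(np.full(n, 2 * sigma ** 2))
               + np.diag(np.full(n - 1, -sigma ** 2), 1)
               + np.diag(np.full(n - 1, -sigma ** 2), -1))
        sign, logdet = np.linalg.slogdet(cov)
        expected = 2 * (-0.5 * (n * np.log(2 * np.pi) + logdet))
        assert np.isclose(cd.rbme_loglik(jumps, 0.0, sigma, dt), expected)

    def test_negative_parameters_rejected(self):
        with pytest.raises(ValueError):
            cd.rbme_loglik(np.zeros((2, 2)), -1.0, 0.03, 0.007)


class TestDefocalizationWeight:
    def test_immobile_molecule_never_exits(self):
        w = cd.defocalization_weight(0.0, 0.00748, 0.7, max_jumps=100)
        assert w == 100.0

    def test_fast_molecule_exits_before_second_frame(self):
        w = cd.defocalization_weight(200.0, 0.00748, 0.7, max_jumps=100)
        assert w < 1.0

    def test_matches_fine_time_step_oracle(self):
        """Per-frame stepping agrees within 2% with an independent
        10-substep random walk observed at frame boundaries."""
        d, dt, dz, cap = 2.5, 0.00748, 0.7, 100
        w = cd.defocalization_weight(d, dt, dz, max_jumps=cap)
        rng = np.random.default_rng(99)
        n, sub = 200_000, 10
        z = rng.uniform(-dz / 2, dz / 2, n)
        alive = np.ones(n, bool)
        jumps = np.zeros(n)
        for _ in range(cap):
            z = z + rng.standard_normal((sub, n)).sum(0) \
                * np.sqrt(2 * d * dt / sub)
            alive &= np.abs(z) <= dz / 2
            jumps += alive
        assert abs(w / jumps.mean() - 1) < 0.02


class TestBoundFraction:
    def test_all_occupation_below_threshold(self):
        grid = np.array([0.02, 2.0])
        assert cd.bound_fraction(np.array([1.0, 0.0]), grid) == 1.0

    def test_mixture_sums_only_slow_states(self):
        grid = np.array([0.05, 2.0])
        assert cd.bound_fraction(np.array([0.4, 0.6]), grid) == 0.4

    def test_threshold_is_strict(self):
        grid = np.array([0.05, 0.1, 2.0])
        occ = np.array([0.3, 0.5, 0.2])
        assert cd.bound_fraction(occ, grid) == pytest.approx(0.3)

    def test_unnormalized_rejected(self):
        with pytest.raises(ValueError):
            cd.bound_fraction(np.array([0.4, 0.4]), np.array([0.05, 2.0]))


class TestStateArrayInfer:
    def test_grid_excludes_threshold(self):
        grid = DiffusionGrid()
        assert not np.any(np.isclose(grid.coefficients, 0.1, rtol=1e-12))
        with pytest.raises(ValueError):
            DiffusionGrid(coefficients=np.array([0.01, 0.1, 1.0]))

    def test_zero_iterations_returns_uniform(self, cfg):
        traj, _ = cd.simulate_trajectories(cd.PRESETS["WT"].two_state, cfg,
                                           1, 50, seed=50)
        spec = cd.state_array_infer(traj, cfg=cfg, max_iter=0)
        k = len(spec.grid)
        assert np.allclose(spec.aggregate, 1.0 / k)
        expected_bf = np.mean(spec.grid < 0.1)
        assert np.isclose(spec.aggregate_bound_fraction(), expected_bf)

    def test_occupations_normalized(self, preset_spectra):
        for spec, _ in preset_spectra.values():
            assert np.allclose(spec.occupations.sum(axis=1), 1.0,
                               atol=1e-9)
            assert np.isclose(spec.aggregate.sum(), 1.0, atol=1e-9)

    def test_single_state_concentrates_on_true_coefficient(self, cfg):
        """Trajectories simulated at one on-grid coefficient put >= 90%
        of aggregate occupation within one grid spacing of it."""
        grid = DiffusionGrid(loc_error=cfg.loc_error)
        d_true = float(grid.coefficients[
            np.argmin(abs(grid.coefficients - 1.05))])
        params = cd.TwoStateParams(f_bound=1.0, d_bound=d_true,
                                   d_free=d_true + 4)
        traj, _ = cd.simulate_trajectories(params, cfg, 2, 1500, seed=51)
        spec = cd.state_array_infer(traj, grid, cfg, max_iter=5000,
                                    tol=1e-9)
        log_dist = np.abs(np.log10(spec.grid) - np.log10(d_true))
        spacing = np.diff(np.log10(spec.grid))[0]
        near = log_dist <= spacing * 1.0001
        assert spec.aggregate[near].sum() >= 0.90

    def test_two_state_mixture_recovery(self, cfg):
        """Recovered bound fraction within +/-0.05 of truth for mixtures
        spanning the bound-fraction and mobility ranges, at 5000
        trajectories each."""
        for i, (f, d_free) in enumerate([(0.2, 10.0), (0.5, 3.0),
                                         (0.8, 1.0)]):
            params = cd.TwoStateParams(f_bound=f, d_free=d_free)
            traj, _ = cd.simulate_trajectories(params, cfg, 5, 1000,
                                               seed=60 + i)
            spec = cd.state_array_infer(traj, cfg=cfg)
            assert abs(spec.aggregate_bound_fraction() - f) <= 0.05, \
                (f, d_free)

    def test_defocalization_correction_reduces_fast_state_bias(self, cfg):
        """The observed-jump weighting moves the fast-state occupation
        toward its true value relative to the uncorrected estimate."""
        params = cd.TwoStateParams(f_bound=0.5, d_free=3.0)
        traj, _ = cd.simulate_trajectories(params, cfg, 5, 1000, seed=12)
        on = 1 - cd.state_array_infer(traj, cfg=cfg) \
            .aggregate_bound_fraction()
        off = 1 - cd.state_array_infer(traj, cfg=cfg,
                                       defocalization=False) \
            .aggregate_bound_fraction()
        assert abs(on - 0.5) < abs(off - 0.5)

    def test_monotone_separation_across_presets(self, preset_spectra):
        """Recovered bound fractions order NLS < G118E < WT < H2B, as the
        generating parameters do."""
        bf = {name: spec.aggregate_bound_fraction()
              for name, (spec, _) in preset_spectra.items()}
        assert bf["NLS"] < bf["G118E"] < bf["WT"] < bf["H2B"]

    def test_no_usable_trajectory_errors(self, cfg):
        traj = pd.DataFrame({"cell_id": "c0", "trajectory": [0],
                             "frame": [0], "x_um": [1.0], "y_um": [1.0]})
        with pytest.raises(ValueError):
            cd.state_array_infer(traj, cfg=cfg)


class TestPerTrajectoryMLE:
    def test_zero_displacement_zero_estimate(self, cfg):
        noiseless = cd.ImagingConfig(loc_error=1e-12)
        traj = pd.DataFrame({"trajectory": 0, "frame": range(5),
                             "x_um": 1.0, "y_um": 1.0})
        mle = cd.per_trajectory_mle(traj, noiseless)
        assert mle.d_mle[0] == pytest.approx(0.0, abs=1e-9)

    def test_exact_jumps_invert_algebraically(self):
        """Jumps of exactly sqrt(4 D dt) with sigma=0 give back D."""
        d, dt = 2.0, 0.00748
        step = np.sqrt(4 * d * dt)
        noiseless = cd.ImagingConfig(loc_error=0.0)
        traj = pd.DataFrame({"trajectory": 0, "frame": range(6),
                             "x_um": np.arange(6) * step, "y_um": 0.0})
        mle = cd.per_trajectory_mle(traj, noiseless)
        assert mle.d_mle[0] == pytest.approx(d, rel=1e-9)

    def test_unbiased_at_scale(self, cfg):
        """Mean estimate over many trajectories at D=3 is within 5% of 3
        after the localization-error correction."""
        params = cd.TwoStateParams(f_bound=1.0, d_bound=3.0, d_free=4.0)
        traj, _ = cd.simulate_trajectories(params, cfg, 1, 10000, seed=55)
        mle = cd.per_trajectory_mle(traj, cfg)
        w = mle["n_jumps"].to_numpy()
        est = (w * mle["d_mle"]).sum() / w.sum()
        assert abs(est / 3.0 - 1) < 0.05
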