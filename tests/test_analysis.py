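"""MSD fitting, survival statistics and exit-angle statistics."""
import math

import numpy as np
import pytest

from porewalk import (
    Channel,
    EnsembleResult,
    MsdCurve,
    SimulationConfig,
    Spherocylinder,
    SurvivalCurve,
    TrajectoryResult,
    UNIFORM_SIGMA,
    angle_distribution,
    angle_sigma,
    compute_msd,
    fit_diffusion,
    fit_lambda,
    survival_curve,
    uniform_orientation_density,
)


def fake_ensemble(position_sets, stride=1, L=1e9):
    """Wrap raw (t, x, y, z) arrays into an EnsembleResult for analysis tests."""
    cfg = SimulationConfig(
        particle=Spherocylinder(l=0.0, d=0.1),
        channel=Channel(L=L),
        seed=0,
        n_traj=len(position_sets),
        record_stride=stride,
        max_steps=10**9,
    )
    trajs = [
        TrajectoryResult(fpt=None, censored=True, exit_theta=None,
                         positions=np.asarray(p, dtype=float),
                         accepted_translations=0, accepted_rotations=0, seed=i)
        for i, p in enumerate(position_sets)
    ]
    return EnsembleResult(config=cfg, trajectories=trajs)


class TestMsd:
    def test_stationary_trajectory_gives_zero(self):
        pos = np.column_stack([np.arange(5), np.zeros(5), np.zeros(5), np.zeros(5)])
        curve = compute_msd(fake_ensemble([pos]))
        assert np.all(curve.msd == 0.0)

    def test_hand_built_average(self):
        # two 3-step trajectories with known displacements
        a = np.array([[0, 0, 0, 0], [1, 1, 0, 0], [2, 0, 2, 0]])
        b = np.array([[0, 0, 0, 0], [1, 0, 0, 3], [2, 0, 0, 4]])
        curve = compute_msd(fake_ensemble([a, b]))
        assert np.allclose(curve.msd, [0.0, (1 + 9) / 2, (4 + 16) / 2])
        assert np.array_equal(curve.n_alive, [2, 2, 2])

    def test_attrition_tracked(self):
        a = np.array([[0, 0, 0, 0], [1, 1, 0, 0]])
        b = np.array([[0, 0, 0, 0], [1, 0, 3, 0], [2, 0, 5, 0]])
        curve = compute_msd(fake_ensemble([a, b]))
        assert np.array_equal(curve.n_alive, [2, 2, 1])
        assert curve.msd[2] == 25.0

    def test_unconfined_gaussian_walk_closed_form(self):
        # 3D walk without walls: msd(t) = 3 sigma_x^2 t, i.e. 2D = 3 sigma_x^2
        rng = np.random.default_rng(17)
        sx, n_steps, n_traj, stride = 0.05, 2000, 1500, 10
        sets = []
        for _ in range(n_traj):
            steps = rng.normal(scale=sx, size=(n_steps, 3))
            walk = np.vstack([np.zeros(3), np.cumsum(steps, axis=0)])[::stride]
            t = np.arange(walk.shape[0]) * stride
            sets.append(np.column_stack([t, walk]))
        curve = compute_msd(fake_ensemble(sets, stride=stride))
        expect = 3 * sx * sx * curve.t[1:]
        assert np.allclose(curve.msd[1:], expect, rtol=0.1)
        fit = fit_diffusion(curve, tmin=n_steps)
        assert fit.alpha == pytest.approx(1.0, abs=0.05)
        assert fit.D == pytest.approx(1.5 * sx * sx, rel=0.1)

    def test_empty_ensemble_rejected(self):
        with pytest.raises(ValueError):
            compute_msd(fake_ensemble([]))


class TestDiffusionFit:
    def test_exact_power_laws_recovered(self):
        t = np.arange(0, 2001, 10)
        for D, alpha in [(0.002, 1.0), (0.001, 0.8)]:
            msd = 2 * D * t.astype(float) ** alpha
            curve = MsdCurve(t=t, msd=msd, n_alive=np.full_like(t, 5))
            fit = fit_diffusion(curve, tmin=2000)
            assert fit.alpha == pytest.approx(alpha, abs=1e-10)
            assert fit.D == pytest.approx(D, rel=1e-10)

    def test_noisy_power_law_bias_small(self):
        rng = np.random.default_rng(1)
        t = np.arange(0, 5001, 10)
        msd = 2 * 0.002 * t.astype(float)
        noisy = msd * (1 + 0.1 * rng.standard_normal(t.size))
        curve = MsdCurve(t=t, msd=np.abs(noisy), n_alive=np.full_like(t, 5))
        fit = fit_diffusion(curve, tmin=5000)
        assert fit.alpha == pytest.approx(1.0, abs=0.02)
        assert fit.D == pytest.approx(0.002, rel=0.05)

    def test_window_too_small_rejected(self):
        t = np.arange(0, 2001, 10)
        curve = MsdCurve(t=t, msd=2 * 0.002 * t.astype(float),
                         n_alive=np.full_like(t, 5))
        with pytest.raises(ValueError, match="grid points"):
            fit_diffusion(curve, tmin=30)


class TestSurvival:
    def test_km_reduces_to_one_minus_ecdf(self):
        curve = survival_curve(np.array([10.0, 20.0, 30.0]))
        lookup = dict(zip(curve.t, curve.S))
        assert lookup[0.0] == 1.0
        assert lookup[10.0] == pytest.approx(2 / 3)
        assert lookup[20.0] == pytest.approx(1 / 3)
        assert lookup[30.0] == pytest.approx(0.0)
        assert np.all(np.diff(curve.S) <= 0)

    def test_censoring_enters_km(self):
        # censored samples keep the curve above the uncensored-only estimate
        t = np.array([10.0, 20.0, 30.0, 30.0])
        ev = np.array([True, True, False, False])
        curve = survival_curve(t, ev)
        assert curve.S[curve.t == 20.0][0] == pytest.approx(0.5)
        assert curve.n_censored == 2

    def test_all_censored_rejected(self):
        with pytest.raises(ValueError):
            survival_curve(np.array([5.0, 5.0]), np.array([False, False]))

    def test_exact_exponential_recovered(self):
        lam = 2e-5
        t = np.linspace(0, 2e5, 2000)
        curve = SurvivalCurve(t=t, S=np.exp(-lam * t), samples=None)
        fit = fit_lambda(curve)
        assert fit.lambda_ == pytest.approx(lam, rel=1e-8)
        assert fit.A == pytest.approx(1.0, rel=1e-6)

    def test_sampled_exponential_recovered(self):
        rng = np.random.default_rng(4)
        lam = 1e-4
        samples = rng.exponential(1 / lam, size=10_000)
        fit = fit_lambda(survival_curve(samples))
        assert fit.lambda_ == pytest.approx(lam, rel=0.05)
        assert fit.median_fpt == pytest.approx(math.log(2) / lam, rel=0.05)

    def test_median_of_integer_samples(self):
        samples = np.arange(1.0, 102.0)
        fit = fit_lambda(survival_curve(samples))
        assert fit.median_fpt == 51

    def test_tail_too_short_rejected(self):
        curve = SurvivalCurve(t=np.linspace(0, 10, 12),
                              S=np.exp(-0.3 * np.linspace(0, 10, 12)), samples=None)
        with pytest.raises(ValueError, match="tail"):
            fit_lambda(curve)


class TestAngles:
    def test_isotropic_orientations_give_flat_density(self, rng):
        # theta with density sin(theta)/2 <-> uniform orientations on the sphere
        # 1e6 draws: the end bins carry only ~0.4% of the sphere measure each,
        # so smaller samples leave them above the 5% flatness band
        theta = np.arccos(1 - 2 * rng.random(1_000_000))
        summ = angle_distribution(theta, n_bins=36)
        assert np.all(np.abs(summ.p_theta - 1 / math.pi) / (1 / math.pi) < 0.05)

    def test_normalization_contract(self, rng):
        theta = np.abs(rng.normal(0.8, 0.3, size=5000)) % math.pi
        summ = angle_distribution(theta, n_bins=36)
        widths = np.diff(summ.bin_edges)
        assert np.sum(summ.p_theta * widths) == pytest.approx(1.0, abs=1e-6)
        assert np.sum(summ.p_raw * widths) == pytest.approx(1.0, abs=1e-6)

    def test_concentrated_spike(self):
        theta = np.full(1000, math.pi / 2) + np.linspace(-0.01, 0.01, 1000)
        summ = angle_distribution(theta, n_bins=35)  # odd: pi/2 is a bin center
        assert (summ.p_theta > 0).sum() == 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            angle_distribution(np.array([]))

    def test_uniform_second_moment(self):
        summ = uniform_orientation_density(n_bins=360)
        assert angle_sigma(summ) == pytest.approx(UNIFORM_SIGMA, rel=1e-3)
        assert UNIFORM_SIGMA == pytest.approx(1.814, abs=5e-4)

    def test_two_point_symmetric_distribution(self):
        # half the weight at each end: sigma -> sqrt(pi^2 / 2)
        n = 720
        edges = np.linspace(0, math.pi, n + 1)
        p = np.zeros(n)
        w = edges[1] - edges[0]
        p[0] = 0.5 / w
        p[-1] = 0.5 / w
        from porewalk import AngleSummary
        summ = AngleSummary(bin_edges=edges, p_theta=p, p_raw=p.copy(), n_samples=0)
        assert angle_sigma(summ) == pytest.approx(math.sqrt(math.pi**2 / 2), rel=5e-3)
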