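"""Oracles and invariances for the TA-MSD and the classical features."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from diffprint import (compute_tamsd, fit_power_law, fractal_dimension,
                       efficiency, gaussianity, kurtosis, mean_msd,
                       mean_step_length, trappedness)
from diffprint.features_classic import classic_features
from diffprint.simulate import SimulationConfig, simulate
from diffprint.types import InsufficientDataError, MsdCurve
from .conftest import make_traj


class TestTamsd:
    def test_three_point_enumeration(self):
        """(0,0),(1,0),(1,1): msd(1) = (1+1)/2 = 1, msd(2) = 2 (one pair)."""
        msd = compute_tamsd(make_traj([(0, 0), (1, 0), (1, 1)]),
                            max_lag_fraction=1.0)
        np.testing.assert_allclose(msd.msd, [1.0, 2.0])
        np.testing.assert_allclose(msd.mqd, [1.0, 4.0])
        np.testing.assert_array_equal(msd.n_pairs, [2, 1])

    def test_ballistic_msd_is_n_squared(self):
        n = 40
        traj = make_traj(np.column_stack([np.arange(n), np.zeros(n)]))
        msd = compute_tamsd(traj, max_lag_fraction=0.25)
        np.testing.assert_allclose(msd.msd, msd.lags_tau ** 2)

    def test_constant_trajectory_msd_zero(self):
        msd = compute_tamsd(make_traj([(2.0, 3.0)] * 10))
        assert np.all(msd.msd == 0)

    def test_too_short_rejected(self):
        with pytest.raises(InsufficientDataError):
            compute_tamsd(make_traj([(0, 0), (1, 1)]))


class TestPowerLawFit:
    @pytest.mark.parametrize("D,alpha", [(4.0, 1.0), (1.0, 2.0), (0.3, 0.5)])
    def test_exact_power_law_recovered(self, D, alpha):
        tau = np.arange(1.0, 11.0)
        curve = MsdCurve(lags_tau=tau, msd=D * tau ** alpha,
                         mqd=3 * (D * tau ** alpha) ** 2,
                         n_pairs=np.full(10, 50))
        fit = fit_power_law(curve)
        assert fit.alpha == pytest.approx(alpha, abs=1e-10)
        assert fit.D_gen == pytest.approx(D, rel=1e-10)
        assert fit.pval_chi2 == pytest.approx(1.0)  # perfect fit

    def test_degenerate_all_zero_msd(self):
        fit = fit_power_law(compute_tamsd(make_traj([(1.0, 1.0)] * 12)))
        assert fit.degenerate
        assert (fit.D_gen, fit.alpha, fit.pval_chi2) == (0.0, 0.0, 0.0)

    def test_brownian_ensemble_alpha_near_one(self):
        trajs, _ = simulate(SimulationConfig(model="brownian", D=1.0,
                                             n_trajectories=300), seed=9)
        alphas = [fit_power_law(compute_tamsd(t)).alpha for t in trajs]
        assert np.mean(alphas) == pytest.approx(1.0, abs=0.1)


class TestFractalDimension:
    def test_straight_line_exactly_one(self, straight_traj):
        assert fractal_dimension(straight_traj) == pytest.approx(1.0, abs=1e-12)

    def test_right_angle_path(self, right_angle_traj):
        # oracle: n=2, L=7, d_max=5 -> log(2)/(log(2)+log(5/7))
        expected = np.log(2) / (np.log(2) + np.log(5.0 / 7.0))
        assert fractal_dimension(right_angle_traj) == pytest.approx(expected)
        assert expected == pytest.approx(1.9431, abs=5e-4)

    def test_coincident_points_flagged(self):
        assert np.isnan(fractal_dimension(make_traj([(0, 0)] * 5)))


class TestEfficiency:
    def test_straight_line_is_one(self, straight_traj):
        assert efficiency(straight_traj) == pytest.approx(1.0)

    def test_closed_loop_is_zero(self):
        square = make_traj([(0, 0), (1, 0), (1, 1), (0, 1), (0, 0)])
        assert efficiency(square) == 0.0

    def test_l_path_manual_value(self):
        # net^2 = 1, (N-1) * sum(step^2) = 3 * 3
        path = make_traj([(0, 0), (1, 0), (1, 1), (0, 1)])
        assert efficiency(path) == pytest.approx(1.0 / 9.0)


class TestTrappedness:
    def test_formula_scalar_oracle(self):
        """Construct a trajectory with known D_short * t / r0^2 = x and
        compare against the direct scalar formula."""
        # straight unit-step path: msd(n) = n^2 so the through-origin fit
        # of lags 1,2 gives D_short = (1*1 + 4*2)/(4*(1+4)) = 9/20
        n = 11
        traj = make_traj(np.column_stack([np.arange(n), np.zeros(n)]))
        msd = compute_tamsd(traj, max_lag_fraction=0.25)
        x = (9.0 / 20.0) * 10.0 / 5.0 ** 2  # D_short * t_total / r0^2
        expected = 1 - np.exp(0.2048 - 0.25117 * x)
        assert trappedness(traj, msd) == pytest.approx(max(expected, 0.0))

    def test_clamped_to_unit_interval(self):
        # x -> 0 gives 1 - e^{0.2048} < 0, clamped to 0
        assert 1 - np.exp(0.2048 - 0.25117 * 4) == pytest.approx(0.55065, abs=1e-4)
        trajs, _ = simulate(SimulationConfig(model="brownian", D=10.0,
                                             n_trajectories=20), seed=0)
        for t in trajs:
            assert 0.0 <= trappedness(t, compute_tamsd(t)) <= 1.0

    def test_coincident_fully_trapped(self):
        traj = make_traj([(0.0, 0.0)] * 10)
        assert trappedness(traj, compute_tamsd(traj)) == 1.0


class TestGaussianityKurtosis:
    def test_gaussianity_single_lag_values(self):
        one = MsdCurve(lags_tau=np.array([1.0]), msd=np.array([1.0]),
                       mqd=np.array([4.0]), n_pairs=np.array([9]))
        assert gaussianity(one) == pytest.approx(1.0)
        const = MsdCurve(lags_tau=np.array([1.0]), msd=np.array([4.0]),
                         mqd=np.array([16.0]), n_pairs=np.array([9]))
        assert gaussianity(const) == pytest.approx(-0.5)  # deterministic steps

    def test_gaussianity_near_zero_for_brownian(self):
        trajs, _ = simulate(SimulationConfig(model="brownian", D=1.0,
                                             n_trajectories=500), seed=10)
        g = [gaussianity(compute_tamsd(t)) for t in trajs]
        assert np.mean(g) == pytest.approx(0.0, abs=0.1)

    def test_kurtosis_normal_reference(self):
        trajs, _ = simulate(SimulationConfig(model="brownian", D=1.0,
                                             n_frames=4000, n_trajectories=1),
                            seed=11)
        assert kurtosis(trajs[0]) == pytest.approx(3.0, abs=0.5)

    def test_kurtosis_two_point_distribution(self):
        # steps alternate +-c along x: mu4 / mu2^2 = 1
        x = np.concatenate([[0], np.cumsum(np.resize([1.0, -1.0], 12))])
        traj = make_traj(np.column_stack([x, np.zeros_like(x)]))
        assert kurtosis(traj) == pytest.approx(1.0)

    def test_kurtosis_needs_four_positions(self):
        with pytest.raises(InsufficientDataError):
            kurtosis(make_traj([(0, 0), (1, 0), (2, 0)]))


def test_mean_step_and_mean_msd():
    traj = make_traj([(0, 0), (1, 0), (1, 1), (2, 1)])
    assert mean_step_length(traj) == 1.0
    curve = MsdCurve(lags_tau=np.array([1.0, 2, 3]),
                     msd=np.array([1.0, 2.0, 3.0]),
                     mqd=np.array([10.0, 10.0, 100.0]),
                     n_pairs=np.array([3, 2, 1]))
    assert mean_msd(curve) == 2.0


@settings(max_examples=20, deadline=None, derandomize=True)
@given(angle=st.floats(0, 2 * np.pi), shift=st.floats(-50, 50),
       seed=st.integers(0, 100))
def test_classic_features_rigid_motion_invariance(angle, shift, seed):
    """Rotating and translating a trajectory changes no classical feature."""
    rng = np.random.default_rng(seed)
    pts = np.cumsum(rng.normal(size=(30, 2)), axis=0)
    R = np.array([[np.cos(angle), -np.sin(angle)],
                  [np.sin(angle), np.cos(angle)]])
    base = classic_features(make_traj(pts))
    moved = classic_features(make_traj(pts @ R.T + shift))
    for name, val in base.items():
        assert moved[name] == pytest.approx(val, rel=1e-8, abs=1e-10), name


def test_classic_features_scale_equivariance():
    rng = np.random.default_rng(12)
    pts = np.cumsum(rng.normal(size=(50, 2)), axis=0)
    c = 3.7
    base = classic_features(make_traj(pts))
    scaled = classic_features(make_traj(pts * c))
    assert scaled["mean_step_length"] == pytest.approx(c * base["mean_step_length"])
    assert scaled["mean_msd"] == pytest.approx(c ** 2 * base["mean_msd"])
    assert scaled["D_gen"] == pytest.approx(c ** 2 * base["D_gen"])
    for inv in ("alpha", "fractal_dimension", "efficiency", "gaussianity",
                "kurtosis"):
        assert scaled[inv] == pytest.approx(base[inv], rel=1e-9), inv
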