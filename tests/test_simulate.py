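"""Motion-simulator statistics: analytic MSD laws, fBm scaling,
confinement bounds, switching ground truth and reproducibility."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist

from diffprint import compute_tamsd, fit_power_law
from diffprint.simulate import (ConfigError, SimulationConfig, StudyDesign,
                                build_synthetic_study, default_study_design,
                                fractional_gaussian_noise, load_study_design,
                                simulate)


def ensemble_msd(trajs):
    return np.mean([compute_tamsd(t).msd for t in trajs], axis=0)


def test_same_seed_bit_identical():
    cfg = SimulationConfig(model="switching", n_trajectories=5,
                           loc_noise_sigma=0.02)
    a, gta = simulate(cfg, seed=42)
    b, gtb = simulate(cfg, seed=42)
    for ta, tb in zip(a, b):
        np.testing.assert_array_equal(ta.x, tb.x)
        np.testing.assert_array_equal(ta.y, tb.y)
    for sa, sb in zip(gta["states"], gtb["states"]):
        np.testing.assert_array_equal(sa, sb)


def test_zero_diffusivity_limit():
    trajs, _ = simulate(SimulationConfig(model="brownian", D=0.0), seed=0)
    assert np.ptp(trajs[0].x) == 0 and np.ptp(trajs[0].y) == 0
    trajs, _ = simulate(SimulationConfig(model="immobile",
                                         loc_noise_sigma=0.0), seed=0)
    assert np.all(trajs[0].positions == 0)


def test_brownian_ensemble_msd_is_4dt():
    """2-D Brownian motion: ensemble TA-MSD(tau) = 4 D tau within 5%."""
    cfg = SimulationConfig(model="brownian", D=1.0, n_trajectories=2000,
                           n_frames=100)
    trajs, _ = simulate(cfg, seed=1)
    msd = ensemble_msd(trajs)
    lags = compute_tamsd(trajs[0]).lags_tau
    np.testing.assert_allclose(msd, 4.0 * lags, rtol=0.05)


def test_fgn_covariance_is_exact():
    """Sample autocovariance of the circulant-embedding fGn matches the
    analytic fGn covariance at small lags."""
    H = 0.75
    rng = np.random.default_rng(3)
    X = np.array([fractional_gaussian_noise(200, H, rng) for _ in range(3000)])
    k = np.arange(4)
    gamma = 0.5 * ((k + 1.0) ** (2 * H) - 2 * k ** (2 * H)
                   + np.abs(k - 1.0) ** (2 * H))
    sample = [np.mean(X[:, :-3] * X[:, lag:200 - 3 + lag]) for lag in k]
    np.testing.assert_allclose(sample, gamma, atol=0.03)


@pytest.mark.parametrize("H", [0.25, 0.5, 0.75])
def test_fbm_loglog_slope_is_2h(H):
    cfg = SimulationConfig(model="fbm", D=1.0, hurst_H=H,
                           n_trajectories=300, n_frames=100)
    trajs, _ = simulate(cfg, seed=2)
    msd = ensemble_msd(trajs)
    lags = compute_tamsd(trajs[0]).lags_tau
    slope = np.polyfit(np.log(lags), np.log(msd), 1)[0]
    assert slope == pytest.approx(2 * H, abs=0.1)


def test_confined_msd_plateaus_within_bound():
    R, noise = 0.5, 0.02
    cfg = SimulationConfig(model="confined", D=1.0, confinement_radius=R,
                           n_trajectories=100, loc_noise_sigma=noise)
    trajs, _ = simulate(cfg, seed=4)
    for t in trajs:
        assert pdist(t.positions).max() <= 2 * R + 6 * noise
    msd = ensemble_msd(trajs)
    # plateau: long-lag MSD stops growing (well under the free 4Dt line)
    assert msd[-1] < 0.2 * 4.0 * compute_tamsd(trajs[0]).lags_tau[-1]
    assert msd[-1] == pytest.approx(msd[len(msd) // 2], rel=0.3)


def test_switching_ground_truth_matches_step_sizes():
    cfg = SimulationConfig(model="switching", state_D=(0.0001, 1.0),
                           n_trajectories=20, n_frames=200)
    trajs, gt = simulate(cfg, seed=5)
    for traj, states in zip(trajs, gt["states"]):
        steps = traj.step_lengths
        assert len(states) == len(steps)
        if 0 < states.sum() < len(states):
            assert steps[states == 1].mean() > 10 * steps[states == 0].mean()


def test_directed_motion_has_net_drift():
    cfg = SimulationConfig(model="directed", D=0.001, drift_speed=0.5,
                           n_frames=100, n_trajectories=50)
    trajs, _ = simulate(cfg, seed=6)
    net = np.array([np.hypot(*(t.positions[-1] - t.positions[0])) for t in trajs])
    assert np.median(net) == pytest.approx(0.5 * 99, rel=0.1)


def test_invalid_configs_rejected():
    with pytest.raises(ConfigError):
        SimulationConfig(model="ballistic")
    with pytest.raises(ConfigError):
        SimulationConfig(model="fbm", hurst_H=1.5)
    with pytest.raises(ConfigError):
        SimulationConfig(model="switching", state_D=(0.1, 1.0),
                         transition_matrix=((0.5, 0.6), (0.1, 0.9)))
    with pytest.raises(ConfigError, match="sum"):
        StudyDesign(mixtures={m: [(0.5, SimulationConfig())]
                              for m in ("PNCM", "PACM-HEC", "PACM-PAA")})


def test_yaml_study_design_roundtrip(tmp_path):
    cfg = tmp_path / "study.yaml"
    cfg.write_text("""
media:
  PNCM:
    - {weight: 0.5, model: immobile}
    - {weight: 0.5, model: brownian, D: 0.2}
  PACM-HEC:
    - {weight: 1.0, model: fbm, D: 0.1, hurst_H: 0.3}
  PACM-PAA:
    - {weight: 1.0, model: confined, D: 0.2, confinement_radius: 0.4}
charges: [negative]
sizes_nm: [200]
n_per_cell: 4
n_frames: 50
loc_noise_sigma: 0.01
""")
    design = load_study_design(cfg)
    assert design.n_per_cell == 4 and design.sizes_nm == (200,)
    trajs, labels = build_synthetic_study(design, seed=0)
    assert len(trajs) == 12 and len(trajs[0]) == 50
    assert set(labels["medium"]) == {"PNCM", "PACM-HEC", "PACM-PAA"}
    with pytest.raises(ConfigError):
        bad = tmp_path / "bad.yaml"
        bad.write_text("just_a_list: []")
        load_study_design(bad)


def test_study_counts_and_labels():
    design = default_study_design("disjoint", n_per_cell=10,
                                  charges=("positive", "negative"),
                                  sizes_nm=(100, 1000))
    trajs, labels = build_synthetic_study(design, seed=0)
    assert len(trajs) == 3 * 2 * 2 * 10
    counts = labels.groupby(["medium", "charge", "nominal_diameter"]).size()
    assert (counts == 10).all()
    assert set(labels["particle_id"]) == {t.particle_id for t in trajs}
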