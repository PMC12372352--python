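"""The ten classical fingerprint features.

All features operate on one trajectory (positions in um) and/or its
time-averaged MSD curve.  Degenerate inputs (zero-variance, coincident
points) yield NaN, which downstream code treats as a flagged value.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from scipy.spatial.distance import pdist

from .msd import compute_tamsd, fit_power_law
from .types import InsufficientDataError, MsdCurve, Trajectory

# Trappedness constants of the fingerprinting literature's empirical
# confinement-probability formula.
_TRAP_A = 0.2048
_TRAP_B = 0.25117


def fractal_dimension(traj: Trajectory) -> float:
    """Katz-George fractal dimension: how space-filling the path is.

    Df = log(n) / (log(n) + log(d_max / L)) with n the number of steps,
    L the total path length and d_max the largest pairwise distance
    between positions.  Exactly 1 for straight ballistic paths, around 2
    for planar Brownian paths, larger for confined/subdiffusive motion.
    """
    if len(traj) < 3:
        raise InsufficientDataError("fractal dimension needs >= 3 positions")
    L = traj.step_lengths.sum()
    if L == 0:
        return np.nan
    d_max = pdist(traj.positions).max()
    n = len(traj) - 1
    return float(np.log(n) / (np.log(n) + np.log(d_max / L)))


def efficiency(traj: Trajectory) -> float:
    """How directly the particle travels from start to finish.

    E = |r_N - r_1|^2 / ((N-1) * sum |r_{i+1} - r_i|^2), in [0, 1]:
    1 for straight equal-step paths, 0 for closed loops.
    """
    steps_sq = (traj.steps ** 2).sum(axis=1)
    denom = (len(traj) - 1) * steps_sq.sum()
    if denom == 0:
        return 0.0
    net = traj.positions[-1] - traj.positions[0]
    return float(net @ net / denom)


def trappedness(traj: Trajectory, msd: MsdCurve) -> float:
    """Probability-like confinement score in [0, 1].

    pt = 1 - exp(0.2048 - 0.25117 * D_short * t_total / r0^2), where
    D_short comes from a through-origin fit MSD = 4 * D_short * tau of
    the first two MSD lags, t_total is the trajectory duration and
    r0 = d_max / 2 is half the maximal extent.  Clamped to [0, 1];
    coincident trajectories (r0 = 0) are fully trapped by convention.
    """
    if len(msd) < 2:
        raise InsufficientDataError("trappedness needs >= 2 MSD lags")
    d_max = pdist(traj.positions).max()
    if d_max == 0:
        return 1.0
    tau = msd.lags_tau[:2]
    m = msd.msd[:2]
    D_short = float((m @ tau) / (4.0 * (tau @ tau)))
    x = D_short * traj.duration / (d_max / 2.0) ** 2
    return float(np.clip(1.0 - np.exp(_TRAP_A - _TRAP_B * x), 0.0, 1.0))


def gaussianity(msd: MsdCurve) -> float:
    """Deviation of displacement moments from the 2-D Gaussian ratio.

    Per lag, g(tau) = <r^4> / (2 <r^2>^2) - 1, which is 0 for Gaussian
    planar displacements (<r^4> = 2 <r^2>^2); the feature is the mean of
    g over the fitted lag range.  Bounded below by -0.5 (Cauchy-Schwarz).
    """
    mask = msd.msd > 0
    if not mask.any():
        return np.nan
    g = msd.mqd[mask] / (2.0 * msd.msd[mask] ** 2) - 1.0
    return float(g.mean())


def kurtosis(traj: Trajectory) -> float:
    """Tailedness of step displacements along the dominant motion axis.

    Steps are projected onto the leading eigenvector of the step
    covariance matrix; the Pearson sample kurtosis of the projections is
    returned (3 for a normal distribution).
    """
    if len(traj) < 4:
        raise InsufficientDataError("kurtosis needs >= 4 positions")
    steps = traj.steps
    cov = np.cov(steps.T)
    w, v = np.linalg.eigh(cov)
    proj = steps @ v[:, np.argmax(w)]
    if np.var(proj) == 0:
        return np.nan
    return float(stats.kurtosis(proj, fisher=False, bias=True))


def mean_step_length(traj: Trajectory) -> float:
    """Mean Euclidean per-frame step length (um)."""
    return float(traj.step_lengths.mean())


def mean_msd(msd: MsdCurve) -> float:
    """Mean of the time-averaged MSD over the fitted lag range (um^2)."""
    return float(msd.msd.mean())


def classic_features(traj: Trajectory, max_lag_fraction: float = 0.25) -> dict:
    """All ten classical features of one trajectory as a name->value dict."""
    msd = compute_tamsd(traj, max_lag_fraction=max_lag_fraction)
    fit = fit_power_law(msd)
    return {
        "D_gen": fit.D_gen if not fit.degenerate else np.nan,
        "alpha": fit.alpha if not fit.degenerate else np.nan,
        "pval_chi2": fit.pval_chi2 if not fit.degenerate else np.nan,
        "fractal_dimension": fractal_dimension(traj),
        "efficiency": efficiency(traj),
        "trappedness": trappedness(traj, msd),
        "gaussianity": gaussianity(msd),
        "kurtosis": kurtosis(traj),
        "mean_step_length": mean_step_length(traj),
        "mean_msd": mean_msd(msd),
    }
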