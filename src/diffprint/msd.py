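"""Time-averaged MSD curves and power-law fitting.

The time-averaged MSD of a single trajectory at lag n*dt is the mean of
|r_{i+n} - r_i|^2 over all start frames i; the quartic analogue (mean of
|r_{i+n} - r_i|^4) feeds the Gaussianity feature.  The scaling exponent
alpha and generalized coefficient D_gen come from an ordinary
least-squares fit of log(MSD) against log(tau): MSD = D_gen * tau^alpha.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .types import InsufficientDataError, MsdCurve, PowerLawFit, Trajectory


def compute_tamsd(traj: Trajectory, max_lag_fraction: float = 0.25) -> MsdCurve:
    """Time-averaged squared and quartic displacement versus lag.

    Lags run from 1 to max(1, floor(N * max_lag_fraction)) frames (capped
    at N-1).  The default fraction 0.25 keeps the long-lag tail, which is
    averaged over very few displacement pairs, out of the fit.
    """
    N = len(traj)
    if N < 3:
        raise InsufficientDataError("need at least 3 positions for a TA-MSD")
    if not 0.0 < max_lag_fraction <= 1.0:
        raise ValueError("max_lag_fraction must be in (0, 1]")
    max_lag = min(N - 1, max(1, int(np.floor(N * max_lag_fraction))))
    pos = traj.positions
    lags = np.arange(1, max_lag + 1)
    msd = np.empty(max_lag)
    mqd = np.empty(max_lag)
    n_pairs = np.empty(max_lag, dtype=np.int64)
    for i, n in enumerate(lags):
        disp = pos[n:] - pos[:-n]
        sq = np.einsum("ij,ij->i", disp, disp)
        msd[i] = sq.mean()
        mqd[i] = (sq ** 2).mean()
        n_pairs[i] = len(sq)
    return MsdCurve(lags_tau=lags * traj.dt, msd=msd, mqd=mqd, n_pairs=n_pairs)


def fit_power_law(msd: MsdCurve) -> PowerLawFit:
    """Fit MSD = D_gen * tau^alpha by OLS in log-log space.

    Zero-MSD lags are excluded.  The goodness of fit is summarized by the
    upper-tail probability of the chi-squared statistic
    sum((msd_obs - msd_fit)^2 / msd_fit) with n_lags - 2 degrees of
    freedom, computed in linear MSD space.  Trajectories whose MSD has
    fewer than 3 positive lags (e.g. noiseless immobile particles) are
    flagged degenerate with D_gen = alpha = pval = 0.
    """
    pos_mask = msd.msd > 0
    if pos_mask.sum() < 3:
        return PowerLawFit(D_gen=0.0, alpha=0.0, pval_chi2=0.0, degenerate=True)
    tau = msd.lags_tau[pos_mask]
    y = msd.msd[pos_mask]
    slope, intercept = np.polyfit(np.log(tau), np.log(y), 1)
    alpha = float(slope)
    D_gen = float(np.exp(intercept))
    fitted = D_gen * tau ** alpha
    chi2_stat = float(np.sum((y - fitted) ** 2 / fitted))
    dof = max(len(tau) - 2, 1)
    pval = float(stats.chi2.sf(chi2_stat, dof))
    return PowerLawFit(D_gen=D_gen, alpha=alpha, pval_chi2=pval)
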