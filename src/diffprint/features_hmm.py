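"""Hidden-Markov state decomposition of trajectories.

A Gaussian-emission HMM is fitted to the 1-D step-length sequence of each
trajectory (step lengths are sign-free and capture mobility directly).
States are relabeled in ascending order of emission mean so occupancies
are comparable across trajectories; the five fingerprint features are the
occupancy fractions T0..T3 of the four ordered states plus the mean dwell
time of the Viterbi-decoded state path.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from hmmlearn.hmm import GaussianHMM

from .types import InsufficientDataError, Trajectory

# hmmlearn's monitor logs every non-monotone EM step; per-trajectory fits
# on 99 steps hit this routinely and harmlessly.
logging.getLogger("hmmlearn.base").setLevel(logging.ERROR)


@dataclass(frozen=True)
class HmmFit:
    """Result of an HMM fit on one trajectory's step lengths.

    States are sorted ascending by emission mean (ties broken by
    variance).  ``occupancies`` has length K, sums to 1, and is the
    fraction of decoded steps per state; ``mean_dwell`` is the mean run
    length (in frames) of the decoded path.  ``converged`` is False when
    every EM restart failed and the single-state fallback was used.
    """

    n_states: int
    means: np.ndarray
    variances: np.ndarray
    transition_matrix: np.ndarray
    state_path: np.ndarray
    occupancies: np.ndarray
    mean_dwell: float
    log_likelihood: float
    converged: bool = True


def _single_state_fit(steps: np.ndarray, K: int) -> HmmFit:
    occ = np.zeros(K)
    occ[0] = 1.0
    return HmmFit(
        n_states=K,
        means=np.full(K, steps.mean()),
        variances=np.full(K, steps.var()),
        transition_matrix=np.eye(K),
        state_path=np.zeros(len(steps), dtype=np.int64),
        occupancies=occ,
        mean_dwell=float(len(steps)),
        log_likelihood=-np.inf,
        converged=False,
    )


def mean_run_length(path: np.ndarray) -> float:
    """Mean length of maximal constant runs in a state sequence."""
    if len(path) == 0:
        return 0.0
    n_runs = 1 + int(np.sum(np.diff(path) != 0))
    return len(path) / n_runs


def fit_hmm(traj: Trajectory, K: int = 4, n_restarts: int = 3,
            seed: int = 0) -> HmmFit:
    """Fit a K-state Gaussian HMM to the step-length sequence by EM.

    ``n_restarts`` random initializations are run and the best
    log-likelihood kept; the decoded (Viterbi) path, occupancy fractions
    and mean dwell time are computed after relabeling states ascending by
    emission mean.  Deterministic given (trajectory, K, seed).  If every
    restart fails (zero-variance steps, EM degeneracy) the flagged
    single-state solution is returned.
    """
    steps = traj.step_lengths
    if len(steps) < K + 2:
        raise InsufficientDataError(
            f"need >= {K + 2} steps for a {K}-state HMM, got {len(steps)}")
    if steps.std() == 0:
        return _single_state_fit(steps, K)
    X = steps[:, None]
    best = None
    for r in range(n_restarts):
        model = GaussianHMM(
            n_components=K, covariance_type="diag", n_iter=100, tol=1e-4,
            min_covar=1e-8, random_state=(seed * 1009 + r) % (2 ** 31))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                model.fit(X)
                ll = model.score(X)
            except (ValueError, np.linalg.LinAlgError):
                continue
        if not np.isfinite(ll):
            continue
        if best is None or ll > best[0]:
            best = (ll, model)
    if best is None:
        return _single_state_fit(steps, K)
    ll, model = best
    means = model.means_.ravel()
    variances = model.covars_.reshape(K, -1)[:, 0]
    order = np.lexsort((variances, means))  # ascending by mean, tie by var
    rank = np.empty(K, dtype=np.int64)
    rank[order] = np.arange(K)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw_path = model.predict(X)
    path = rank[raw_path]
    occupancies = np.bincount(path, minlength=K) / len(path)
    return HmmFit(
        n_states=K,
        means=means[order],
        variances=variances[order],
        transition_matrix=model.transmat_[np.ix_(order, order)],
        state_path=path,
        occupancies=occupancies,
        mean_dwell=mean_run_length(path),
        log_likelihood=float(ll),
        converged=bool(model.monitor_.converged),
    )


def hmm_fingerprint(fit: HmmFit) -> dict:
    """The five HMM fingerprint features: T0..T3 occupancies + mean dwell.

    States never decoded have occupancy 0.  For fits with K != 4 the
    occupancy vector is truncated/zero-padded to four entries so the
    fingerprint schema stays fixed.
    """
    occ = np.zeros(4)
    k = min(4, fit.n_states)
    occ[:k] = fit.occupancies[:k]
    return {"T0": occ[0], "T1": occ[1], "T2": occ[2], "T3": occ[3],
            "mean_dwell": fit.mean_dwell}
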