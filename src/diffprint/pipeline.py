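"""Fingerprint assembly, dataset categorization, standardization and
diffusion-mode classification.

One trajectory yields a 20-feature fingerprint row: ten classical
descriptors, five hidden-Markov state features and five trajectory
microrheology features.  Rows with any flagged (NaN) feature carry
``flagged=True`` and are excluded from machine learning by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.preprocessing import StandardScaler

from . import features_classic as fc
from .features_hmm import fit_hmm, hmm_fingerprint
from .microrheology import LOW_FREQ_BAND, default_s0_grid, rheology_features
from .msd import compute_tamsd, fit_power_law
from .types import (CHARGES, FEATURE_NAMES, MEDIA, SIZES_NM, MsdCurve,
                    ParticleContext, Trajectory)

MODES = ("immobile", "subdiffusive", "diffusive", "active")


@dataclass(frozen=True)
class FingerprintConfig:
    """Knobs of the fingerprint computation (defaults used throughout)."""

    max_lag_fraction: float = 0.25
    hmm_states: int = 4
    hmm_restarts: int = 3
    s0_points: int = 60
    low_freq_band: tuple = LOW_FREQ_BAND
    seed: int = 0


def fingerprint(traj: Trajectory, ctx: ParticleContext,
                config: FingerprintConfig = FingerprintConfig()) -> dict:
    """The 20 named feature values of one trajectory.

    Deterministic given (trajectory, context, config).  Degenerate
    sub-computations yield NaN entries rather than raising.
    """
    msd = compute_tamsd(traj, max_lag_fraction=config.max_lag_fraction)
    fit = fit_power_law(msd)
    row = {
        "D_gen": fit.D_gen if not fit.degenerate else np.nan,
        "alpha": fit.alpha if not fit.degenerate else np.nan,
        "pval_chi2": fit.pval_chi2 if not fit.degenerate else np.nan,
        "fractal_dimension": fc.fractal_dimension(traj),
        "efficiency": fc.efficiency(traj),
        "trappedness": fc.trappedness(traj, msd),
        "gaussianity": fc.gaussianity(msd),
        "kurtosis": fc.kurtosis(traj),
        "mean_step_length": fc.mean_step_length(traj),
        "mean_msd": fc.mean_msd(msd),
    }
    hmm = fit_hmm(traj, K=config.hmm_states, n_restarts=config.hmm_restarts,
                  seed=config.seed)
    row.update(hmm_fingerprint(hmm))
    row.update(rheology_features(
        msd, fit, ctx, s0_grid=default_s0_grid(config.s0_points),
        low_freq_band=config.low_freq_band))
    return row


def fingerprint_table(trajectories, labels: pd.DataFrame,
                      config: FingerprintConfig = FingerprintConfig(),
                      temperature_T: float = 310.15) -> pd.DataFrame:
    """Fingerprint a labeled trajectory collection.

    ``labels`` must carry particle_id, medium, charge and
    nominal_diameter (nm); the particle radius for the microrheology
    features is nominal_diameter / 2.  Returns one row per trajectory
    with label columns, the 20 features and a ``flagged`` column marking
    rows with any NaN feature.
    """
    lab = labels.set_index("particle_id")
    rows = []
    for traj in trajectories:
        meta = lab.loc[traj.particle_id]
        ctx = ParticleContext.from_diameter_nm(
            float(meta["nominal_diameter"]), charge=meta["charge"],
            medium=meta["medium"], temperature_T=temperature_T)
        row = {"particle_id": traj.particle_id, "medium": meta["medium"],
               "charge": meta["charge"],
               "nominal_diameter": int(meta["nominal_diameter"])}
        row.update(fingerprint(traj, ctx, config))
        rows.append(row)
    table = pd.DataFrame(rows)
    table["flagged"] = table[FEATURE_NAMES].isna().any(axis=1)
    return table


# ---------------------------------------------------------------------------
# Data categories (charge / size subsets)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CategorySpec:
    """A dataset category: a charge filter and a size filter."""

    name: str
    charges: tuple
    sizes_nm: tuple

    def mask(self, table: pd.DataFrame) -> pd.Series:
        return (table["charge"].isin(self.charges)
                & table["nominal_diameter"].isin(self.sizes_nm))


def _canonical_categories() -> list[CategorySpec]:
    cats = [CategorySpec("All Data", CHARGES, SIZES_NM)]
    for charge in ("positive", "negative"):
        cats.append(CategorySpec(f"{charge.capitalize()}ly charged",
                                 (charge,), SIZES_NM))
    for charge in ("positive", "negative"):
        for size in SIZES_NM:
            cats.append(CategorySpec(
                f"{charge.capitalize()}ly charged {size} nm", (charge,), (size,)))
    return cats


#: The nine canonical categories: all data, per-charge, per charge x size.
CATEGORIES = {c.name: c for c in _canonical_categories()}


def categorize(table: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Split a fingerprint table into the nine canonical categories."""
    bad_charge = set(table["charge"]) - set(CHARGES)
    bad_size = set(table["nominal_diameter"]) - set(SIZES_NM)
    if bad_charge or bad_size:
        raise ValueError(
            f"unknown label values: charges {bad_charge or '{}'}, "
            f"sizes {bad_size or '{}'}")
    return {name: table[spec.mask(table)].reset_index(drop=True)
            for name, spec in CATEGORIES.items()}


# ---------------------------------------------------------------------------
# Diffusion modes from the scaling exponent
# ---------------------------------------------------------------------------

def classify_mode(alpha: float) -> str:
    """Diffusion mode from the fitted scaling exponent.

    immobile: alpha < 0; subdiffusive: 0 <= alpha < 1;
    diffusive: 1 <= alpha <= 2; active: alpha > 2.
    """
    if np.isnan(alpha):
        raise ValueError("alpha is flagged/NaN; exclude before classification")
    if alpha < 0:
        return "immobile"
    if alpha < 1:
        return "subdiffusive"
    if alpha <= 2:
        return "diffusive"
    return "active"


def mode_fractions(table: pd.DataFrame,
                   by=("medium", "charge", "nominal_diameter")) -> pd.DataFrame:
    """Percentage of trajectories per diffusion mode within each group.

    Rows with flagged alpha are excluded (their count is reported in the
    ``n_excluded`` column).  Mode percentages sum to 100 per group.
    """
    by = list(by)
    rows = []
    for keys, grp in table.groupby(by, sort=True, observed=True):
        keys = keys if isinstance(keys, tuple) else (keys,)
        valid = grp["alpha"].dropna()
        counts = valid.map(classify_mode).value_counts()
        row = dict(zip(by, keys))
        total = len(valid)
        for mode in MODES:
            row[mode] = 100.0 * counts.get(mode, 0) / total if total else np.nan
        row["n"] = total
        row["n_excluded"] = len(grp) - total
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Standardization
# ---------------------------------------------------------------------------

def standardize(table: pd.DataFrame, scaler: StandardScaler | None = None,
                features: list[str] | None = None):
    """Z-score the feature columns (mean 0, variance 1 on the fitting set).

    With ``scaler=None`` a new scaler is fitted on ``table`` (this is the
    'global' order of operations when applied before splitting); passing
    a fitted scaler applies it to held-out rows.  Zero-variance features
    are dropped from the output with a recorded warning.  Returns
    ``(standardized_table, scaler, kept_features)``.
    """
    if len(table) < 2 and scaler is None:
        raise ValueError("need >= 2 rows to fit a standardizer")
    features = list(features or FEATURE_NAMES)
    if scaler is None:
        variances = table[features].var(ddof=0)
        kept = [f for f in features if variances[f] > 0]
        if len(kept) < len(features):
            import warnings
            warnings.warn(
                f"dropped zero-variance feature(s): "
                f"{sorted(set(features) - set(kept))}")
        scaler = StandardScaler().fit(table[kept].to_numpy())
        scaler.feature_names_ = kept
    kept = scaler.feature_names_
    out = table.copy()
    out[kept] = scaler.transform(table[kept].to_numpy())
    out = out.drop(columns=[f for f in features if f not in kept])
    return out, scaler, kept
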