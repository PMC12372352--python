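"""Core domain types for diffusional fingerprinting.

Internal length unit is micrometers throughout; the microrheology module
converts to SI (meters) where the generalized Stokes-Einstein relation
requires it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Canonical class labels: one native porcine colonic mucus and two
#: artificial colonic mucus models (hydroxyethyl-cellulose- and
#: polyacrylic-acid-based).
MEDIA = ("PNCM", "PACM-HEC", "PACM-PAA")
CHARGES = ("positive", "negative")
SIZES_NM = (100, 200, 1000)

#: Fixed column order of the 20 fingerprint features.
FEATURE_NAMES = [
    # classical trajectory descriptors
    "D_gen", "alpha", "pval_chi2", "fractal_dimension", "efficiency",
    "trappedness", "gaussianity", "kurtosis", "mean_step_length", "mean_msd",
    # hidden-Markov state features
    "T0", "T1", "T2", "T3", "mean_dwell",
    # trajectory microrheology
    "mean_J", "mean_Gstar", "mean_Gprime", "mean_Gdoubleprime", "mean_eta",
]

LABEL_COLUMNS = ["particle_id", "medium", "charge", "nominal_diameter"]


class TrajectoryError(ValueError):
    """Raised for malformed trajectory input."""


class InsufficientDataError(TrajectoryError):
    """Raised when a trajectory is too short for the requested computation."""


@dataclass(frozen=True)
class Trajectory:
    """An ordered 2-D single-particle track.

    Parameters
    ----------
    particle_id : opaque identifier of the particle.
    frames : strictly increasing integer frame indices.
    x, y : positions in micrometers.
    dt : frame interval in seconds (1 s for 1 Hz acquisition).
    """

    particle_id: object
    frames: np.ndarray
    x: np.ndarray
    y: np.ndarray
    dt: float = 1.0

    def __post_init__(self):
        frames = np.asarray(self.frames, dtype=np.int64)
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if not (len(frames) == len(x) == len(y)):
            raise TrajectoryError(
                f"particle {self.particle_id}: frames/x/y length mismatch")
        if len(frames) < 2:
            raise InsufficientDataError(
                f"particle {self.particle_id}: need >= 2 positions")
        if np.any(np.diff(frames) <= 0):
            raise TrajectoryError(
                f"particle {self.particle_id}: frame indices not strictly increasing")
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
            raise TrajectoryError(
                f"particle {self.particle_id}: non-finite positions")
        if self.dt <= 0:
            raise TrajectoryError("dt must be positive")
        object.__setattr__(self, "frames", frames)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def positions(self) -> np.ndarray:
        """(N, 2) array of positions in micrometers."""
        return np.column_stack([self.x, self.y])

    @property
    def steps(self) -> np.ndarray:
        """(N-1, 2) array of per-frame displacement vectors."""
        return np.diff(self.positions, axis=0)

    @property
    def step_lengths(self) -> np.ndarray:
        """(N-1,) Euclidean per-frame step lengths in micrometers."""
        return np.hypot(np.diff(self.x), np.diff(self.y))

    @property
    def duration(self) -> float:
        """Total tracked time span in seconds."""
        return (self.frames[-1] - self.frames[0]) * self.dt


@dataclass(frozen=True)
class ParticleContext:
    """Physical context of a tracked particle, as needed by the
    generalized Stokes-Einstein relation.

    radius_a is in meters, temperature_T in kelvin (default 310.15 K,
    i.e. 37 degC), dimensionality_d is 2 for planar tracking.
    """

    radius_a: float
    charge: str = "negative"
    nominal_diameter: int = 200
    medium: str | None = None
    temperature_T: float = 310.15
    dimensionality_d: int = 2

    def __post_init__(self):
        if self.radius_a <= 0:
            raise ValueError("radius_a must be > 0")
        if self.temperature_T <= 0:
            raise ValueError("temperature_T must be > 0")
        if self.dimensionality_d not in (2, 3):
            raise ValueError("dimensionality_d must be 2 or 3")

    @classmethod
    def from_diameter_nm(cls, diameter_nm: float, **kwargs) -> "ParticleContext":
        """Build a context from a nominal particle diameter in nanometers."""
        return cls(radius_a=diameter_nm * 1e-9 / 2.0,
                   nominal_diameter=int(diameter_nm), **kwargs)


@dataclass(frozen=True)
class MsdCurve:
    """Time-averaged mean squared (and quartic) displacement versus lag.

    lags_tau in seconds, msd in um^2, mqd in um^4; n_pairs counts the
    displacement pairs averaged at each lag.
    """

    lags_tau: np.ndarray
    msd: np.ndarray
    mqd: np.ndarray
    n_pairs: np.ndarray

    def __post_init__(self):
        lags = np.asarray(self.lags_tau, dtype=float)
        msd = np.asarray(self.msd, dtype=float)
        mqd = np.asarray(self.mqd, dtype=float)
        n_pairs = np.asarray(self.n_pairs, dtype=np.int64)
        if np.any(np.diff(lags) <= 0):
            raise ValueError("lags must be strictly increasing")
        if np.any(msd < 0):
            raise ValueError("msd must be non-negative")
        # Cauchy-Schwarz: <r^4> >= <r^2>^2 (allow float slack)
        if np.any(mqd < msd ** 2 - 1e-9 * np.maximum(mqd, 1.0)):
            raise ValueError("mqd < msd^2 violates Cauchy-Schwarz")
        for name, arr in (("lags_tau", lags), ("msd", msd),
                          ("mqd", mqd), ("n_pairs", n_pairs)):
            object.__setattr__(self, name, arr)

    def __len__(self) -> int:
        return len(self.lags_tau)


@dataclass(frozen=True)
class PowerLawFit:
    """Power-law fit MSD = D_gen * tau^alpha of a time-averaged MSD curve.

    D_gen is in um^2 s^-alpha; alpha is the log-log slope; pval_chi2 is
    the upper-tail chi-squared goodness-of-fit probability. ``degenerate``
    marks trajectories (e.g. noiseless immobile particles) whose MSD
    cannot support a fit; their D_gen/alpha/pval are reported as 0.
    """

    D_gen: float
    alpha: float
    pval_chi2: float
    degenerate: bool = False

    def __post_init__(self):
        if not self.degenerate:
            if self.D_gen <= 0:
                raise ValueError("D_gen must be > 0 for a successful fit")
            if not 0.0 <= self.pval_chi2 <= 1.0:
                raise ValueError("pval_chi2 must be in [0, 1]")
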