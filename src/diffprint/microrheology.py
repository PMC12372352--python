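"""Trajectory-based passive microrheology via the generalized
Stokes-Einstein relation.

From a tracer's time-averaged MSD the medium's linear viscoelastic
response is estimated:

* creep compliance  J(tau) = 3 pi a / (d k_B T) * <dr^2(tau)>   [Pa^-1]
* complex modulus   G*(s0) = d k_B T / (3 pi a <dr^2(t0)> Gamma(alpha+1)),
  with t0 = 1/s0 and <dr^2(t0)> extrapolated from the global power-law
  fit MSD = D_gen t^alpha                                       [Pa]
* storage/loss      G'(w) = |G*| cos(pi alpha / 2),
                    G''(w) = |G*| sin(pi alpha / 2)             [Pa]
* viscosity         eta(w) = G''(w) / w in the low-frequency limit [Pa s]

Here a is the particle radius (m), d the dimensionality, k_B Boltzmann's
constant and T the temperature (K).  MSD curves arrive in um^2 and are
converted to m^2 internally.  The Laplace-frequency grid spans
s0 in [0.01, 100] s^-1 (60 log-spaced points by default); because
measured lags start at dt, the s0 > 1/dt half of the grid relies on the
power-law extrapolation of the MSD to sub-resolution times.

The scaling exponent is clamped to [1e-3, 2] before evaluating the gamma
function and the cos/sin factors; immobile trajectories with slightly
negative fitted alpha thus receive near-elastic (alpha -> 0) moduli
rather than values outside the physical branch.  For alpha > 1 the
storage modulus G' is negative by the sign convention of the cos factor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.constants import k as KB
from scipy.special import gamma as gamma_fn

from .types import MsdCurve, ParticleContext, PowerLawFit

UM2_TO_M2 = 1e-12

ALPHA_MIN = 1e-3
ALPHA_MAX = 2.0

#: Default Laplace-frequency grid, s^-1.
S0_RANGE = (0.01, 100.0)
S0_POINTS = 60

#: Default low-frequency band for the viscosity estimate (lowest decade).
LOW_FREQ_BAND = (0.01, 0.1)


def default_s0_grid(n: int = S0_POINTS) -> np.ndarray:
    return np.logspace(np.log10(S0_RANGE[0]), np.log10(S0_RANGE[1]), n)


@dataclass(frozen=True)
class RheologySpectrum:
    """Frequency-resolved microrheology of one trajectory."""

    s0_grid: np.ndarray          # Laplace frequencies, s^-1 (= omega grid)
    Gstar: np.ndarray            # Pa
    Gprime: np.ndarray           # Pa
    Gdoubleprime: np.ndarray     # Pa
    eta: np.ndarray              # Pa s, over the low-frequency band
    J_lags: np.ndarray           # s
    J_curve: np.ndarray          # Pa^-1 per measured lag
    alpha_clamped: bool

    @property
    def t0_grid(self) -> np.ndarray:
        return 1.0 / self.s0_grid


def _thermal_prefactor(ctx: ParticleContext) -> float:
    """3 pi a / (d k_B T) in SI units (Pa^-1 m^-2)."""
    return 3.0 * np.pi * ctx.radius_a / (ctx.dimensionality_d * KB * ctx.temperature_T)


def creep_compliance(msd: MsdCurve, ctx: ParticleContext):
    """Creep compliance J(tau) per measured lag and its mean over all lags.

    J is directly proportional to the MSD, so it inherits the MSD's
    shape: linear in tau for a Newtonian fluid (J = tau / eta).
    Returns ``(J_curve, mean_J)`` in Pa^-1.
    """
    J = _thermal_prefactor(ctx) * msd.msd * UM2_TO_M2
    return J, float(J.mean())


def complex_modulus(fit: PowerLawFit, ctx: ParticleContext,
                    s0_grid: np.ndarray | None = None):
    """|G*| over the Laplace-frequency grid and its mean.

    The MSD at t0 = 1/s0 is evaluated from the fitted power law
    D_gen * t0^alpha (alpha clamped to [1e-3, 2]).  Returns
    ``(Gstar, mean_Gstar, alpha_used, clamped)``.
    """
    if fit.degenerate:
        raise ValueError("cannot compute moduli from a degenerate power-law fit")
    if s0_grid is None:
        s0_grid = default_s0_grid()
    alpha = float(np.clip(fit.alpha, ALPHA_MIN, ALPHA_MAX))
    clamped = alpha != fit.alpha
    t0 = 1.0 / s0_grid
    msd_t0 = fit.D_gen * UM2_TO_M2 * t0 ** alpha  # m^2
    Gstar = 1.0 / (_thermal_prefactor(ctx) * msd_t0 * gamma_fn(alpha + 1.0))
    return Gstar, float(Gstar.mean()), alpha, clamped


def storage_loss(Gstar: np.ndarray, alpha: float):
    """Split |G*| into storage and loss moduli.

    G'(w) = |G*| cos(pi alpha / 2), G''(w) = |G*| sin(pi alpha / 2).
    Returns ``(Gprime, Gdoubleprime, mean_Gprime, mean_Gdoubleprime)``.
    """
    Gp = Gstar * np.cos(np.pi * alpha / 2.0)
    Gpp = Gstar * np.sin(np.pi * alpha / 2.0)
    return Gp, Gpp, float(Gp.mean()), float(Gpp.mean())


def viscosity(Gdoubleprime: np.ndarray, omega_grid: np.ndarray,
              low_freq_band: tuple = LOW_FREQ_BAND):
    """eta(w) = G''(w) / w averaged over the low-frequency band.

    Returns ``(eta_band, mean_eta)``; eta_band covers the frequencies
    inside ``low_freq_band`` (default: the lowest decade of the grid).
    """
    mask = (omega_grid >= low_freq_band[0]) & (omega_grid <= low_freq_band[1])
    if not mask.any():
        raise ValueError("low_freq_band contains no grid frequencies")
    eta = Gdoubleprime[mask] / omega_grid[mask]
    return eta, float(eta.mean())


def elastic_viscous_ratio(mean_Gprime: float, mean_Gdoubleprime: float) -> float:
    """G'/G'' ratio; > 1 indicates solid-like (elastic) dominance.

    Equals cot(pi alpha / 2) under the power-law model, hence > 1 exactly
    when alpha < 0.5.  NaN when the loss modulus vanishes.
    """
    if mean_Gdoubleprime == 0:
        return np.nan
    return mean_Gprime / mean_Gdoubleprime


def rheology_spectrum(msd: MsdCurve, fit: PowerLawFit, ctx: ParticleContext,
                      s0_grid: np.ndarray | None = None,
                      low_freq_band: tuple = LOW_FREQ_BAND) -> RheologySpectrum:
    """Full frequency-resolved microrheology of one trajectory."""
    if s0_grid is None:
        s0_grid = default_s0_grid()
    J, _ = creep_compliance(msd, ctx)
    Gstar, _, alpha, clamped = complex_modulus(fit, ctx, s0_grid)
    Gp, Gpp, _, _ = storage_loss(Gstar, alpha)
    eta, _ = viscosity(Gpp, s0_grid, low_freq_band)
    return RheologySpectrum(s0_grid=s0_grid, Gstar=Gstar, Gprime=Gp,
                            Gdoubleprime=Gpp, eta=eta, J_lags=msd.lags_tau,
                            J_curve=J, alpha_clamped=clamped)


def rheology_features(msd: MsdCurve, fit: PowerLawFit, ctx: ParticleContext,
                      s0_grid: np.ndarray | None = None,
                      low_freq_band: tuple = LOW_FREQ_BAND) -> dict:
    """The five rheological fingerprint features of one trajectory.

    Degenerate power-law fits yield NaN for every feature (flagged row).
    """
    if fit.degenerate:
        return {k: np.nan for k in ("mean_J", "mean_Gstar", "mean_Gprime",
                                    "mean_Gdoubleprime", "mean_eta")}
    if s0_grid is None:
        s0_grid = default_s0_grid()
    _, mean_J = creep_compliance(msd, ctx)
    Gstar, mean_Gstar, alpha, _ = complex_modulus(fit, ctx, s0_grid)
    _, Gpp, mean_Gp, mean_Gpp = storage_loss(Gstar, alpha)
    _, mean_eta = viscosity(Gpp, s0_grid, low_freq_band)
    return {"mean_J": mean_J, "mean_Gstar": mean_Gstar,
            "mean_Gprime": mean_Gp, "mean_Gdoubleprime": mean_Gpp,
            "mean_eta": mean_eta}
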