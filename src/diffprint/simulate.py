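"""Synthetic 2-D motion models standing in for particle-tracking videos.

Generates labeled trajectories with the statistical structure the
fingerprinting analysis assumes: pure Brownian motion, fractional Brownian
motion (anomalous diffusion with MSD ~ t^{2H}), confined diffusion inside a
reflecting circular domain, directed motion with drift, immobile particles,
and hidden-Markov switching between mobility states.  Independent Gaussian
localization noise is added to every observed position, matching the
standard static tracking-error model.

Units: positions in micrometers, D in um^2/s, time in seconds.  Per-axis
increments of Brownian motion have variance 2*D*dt, so the 2-D ensemble
MSD is 4*D*tau; the fBm generalization uses per-axis increment variance
2*D*dt^{2H}, giving MSD = 4*D*tau^{2H} and a fitted scaling exponent
alpha = 2H.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .types import CHARGES, MEDIA, SIZES_NM, Trajectory

MODELS = ("brownian", "fbm", "confined", "directed", "immobile", "switching")


class ConfigError(ValueError):
    """Raised for invalid simulation configuration."""


@dataclass(frozen=True)
class SimulationConfig:
    """Configuration of one motion model.

    Defaults mirror the emulated acquisition: 100-frame trajectories at
    1 Hz.  ``loc_noise_sigma`` is the standard deviation (um) of the
    Gaussian localization error added to every observed coordinate.
    """

    model: str = "brownian"
    n_trajectories: int = 1
    n_frames: int = 100
    dt: float = 1.0
    D: float = 0.1                      # um^2/s
    hurst_H: float = 0.5                # fbm only
    confinement_radius: float = 0.5     # um, confined only
    drift_speed: float = 0.05           # um/s, directed only
    state_D: tuple = (0.01, 1.0)        # um^2/s, switching only
    transition_matrix: tuple = ((0.9, 0.1), (0.1, 0.9))
    loc_noise_sigma: float = 0.0        # um
    D_sigma: float = 0.0                # lognormal dispersion of D per trajectory
    seed: int | None = None

    def __post_init__(self):
        if self.model not in MODELS:
            raise ConfigError(f"unknown model {self.model!r}; one of {MODELS}")
        if self.n_trajectories < 1 or self.n_frames < 2:
            raise ConfigError("need n_trajectories >= 1 and n_frames >= 2")
        if self.dt <= 0:
            raise ConfigError("dt must be > 0")
        if self.D < 0 or self.loc_noise_sigma < 0 or self.D_sigma < 0:
            raise ConfigError("D, loc_noise_sigma and D_sigma must be >= 0")
        if self.model == "fbm" and not 0.0 < self.hurst_H < 1.0:
            raise ConfigError("hurst_H must be in (0, 1)")
        if self.model == "confined" and self.confinement_radius <= 0:
            raise ConfigError("confinement_radius must be > 0")
        if self.model == "switching":
            P = np.asarray(self.transition_matrix, dtype=float)
            if np.any(np.asarray(self.state_D) < 0):
                raise ConfigError("state diffusivities must be >= 0")
            if P.shape != (len(self.state_D),) * 2:
                raise ConfigError("transition matrix shape must match state_D")
            if np.any(P < 0) or not np.allclose(P.sum(axis=1), 1.0):
                raise ConfigError("transition matrix rows must sum to 1")


def fractional_gaussian_noise(n: int, H: float, rng: np.random.Generator) -> np.ndarray:
    """Exact fractional Gaussian noise of length n via circulant embedding.

    Davies-Harte construction: embed the fGn autocovariance
    gamma(k) = (|k+1|^{2H} - 2|k|^{2H} + |k-1|^{2H}) / 2 in a circulant
    matrix whose eigenvalues (computed by FFT) are provably non-negative
    for 0 < H < 1, then color complex white noise.  Returns unit-variance
    increments with the exact fGn covariance (no approximation bias in
    the recovered scaling exponent).
    """
    if n == 1:
        return rng.standard_normal(1)
    k = np.arange(0, n)
    gamma = 0.5 * (np.abs(k + 1) ** (2 * H) - 2 * np.abs(k) ** (2 * H)
                   + np.abs(k - 1) ** (2 * H))
    # first row of the 2(n-1)-circulant embedding
    row = np.concatenate([gamma, gamma[-2:0:-1]])
    eigs = np.fft.fft(row).real
    eigs = np.maximum(eigs, 0.0)  # clip float-level negatives
    m = len(row)
    z = rng.standard_normal(m) + 1j * rng.standard_normal(m)
    coeff = np.sqrt(eigs / (2.0 * m))
    fgn = np.fft.fft(coeff * z)[:n].real * np.sqrt(2.0)
    return fgn


def _disperse(config: SimulationConfig, rng: np.random.Generator) -> SimulationConfig:
    """Draw this trajectory's diffusivity from a lognormal around config.D.

    ``D_sigma`` is the log-space standard deviation; it models the spread
    of local diffusivities a heterogeneous medium presents to otherwise
    identical particles.  With D_sigma = 0 the config is returned as is.
    """
    if config.D_sigma == 0:
        return config
    m = float(np.exp(config.D_sigma * rng.standard_normal()))
    return replace(config, D=config.D * m,
                   state_D=tuple(d * m for d in config.state_D))


def _positions(config: SimulationConfig, rng: np.random.Generator):
    """True (noise-free) positions for one trajectory, plus per-frame states."""
    n = config.n_frames
    dt = config.dt
    states = None
    if config.model == "immobile":
        pos = np.zeros((n, 2))
    elif config.model == "brownian":
        steps = rng.standard_normal((n - 1, 2)) * np.sqrt(2 * config.D * dt)
        pos = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
    elif config.model == "directed":
        theta = rng.uniform(0, 2 * np.pi)
        drift = config.drift_speed * dt * np.array([np.cos(theta), np.sin(theta)])
        steps = rng.standard_normal((n - 1, 2)) * np.sqrt(2 * config.D * dt) + drift
        pos = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
    elif config.model == "fbm":
        scale = np.sqrt(2 * config.D) * dt ** config.hurst_H
        incs = np.column_stack([
            fractional_gaussian_noise(n - 1, config.hurst_H, rng),
            fractional_gaussian_noise(n - 1, config.hurst_H, rng),
        ]) * scale
        pos = np.vstack([[0.0, 0.0], np.cumsum(incs, axis=0)])
    elif config.model == "confined":
        R = config.confinement_radius
        pos = np.zeros((n, 2))
        cur = np.zeros(2)
        steps = rng.standard_normal((n - 1, 2)) * np.sqrt(2 * config.D * dt)
        for i, s in enumerate(steps, start=1):
            cur = cur + s
            r = np.hypot(*cur)
            while r > R:  # radial reflection at the boundary
                cur = cur * (2 * R - r) / r
                r = abs(2 * R - r)
            pos[i] = cur
    elif config.model == "switching":
        P = np.asarray(config.transition_matrix, dtype=float)
        K = len(config.state_D)
        # start from the stationary distribution of the chain
        w, v = np.linalg.eig(P.T)
        pi = np.abs(v[:, np.argmin(np.abs(w - 1.0))].real)
        pi = pi / pi.sum()
        states = np.empty(n - 1, dtype=np.int64)
        states[0] = rng.choice(K, p=pi)
        for i in range(1, n - 1):
            states[i] = rng.choice(K, p=P[states[i - 1]])
        sigma = np.sqrt(2 * np.asarray(config.state_D)[states] * dt)
        steps = rng.standard_normal((n - 1, 2)) * sigma[:, None]
        pos = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
    else:  # pragma: no cover - guarded by __post_init__
        raise ConfigError(config.model)
    return pos, states


def simulate(config: SimulationConfig, seed: int | None = None):
    """Simulate labeled trajectories under one motion model.

    Returns ``(trajectories, ground_truth)`` where ground_truth is a dict
    with the model name per trajectory and, for the switching model, the
    per-frame hidden state sequence (length n_frames - 1, one state per
    step) of each trajectory.  Identical seeds give bit-identical output.
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    trajectories = []
    state_paths = []
    for i in range(config.n_trajectories):
        pos, states = _positions(_disperse(config, rng), rng)
        if config.loc_noise_sigma > 0:
            pos = pos + rng.standard_normal(pos.shape) * config.loc_noise_sigma
        trajectories.append(Trajectory(
            particle_id=i,
            frames=np.arange(config.n_frames),
            x=pos[:, 0], y=pos[:, 1], dt=config.dt,
        ))
        state_paths.append(states)
    ground_truth = {"model": [config.model] * config.n_trajectories}
    if config.model == "switching":
        ground_truth["states"] = state_paths
    return trajectories, ground_truth


# ---------------------------------------------------------------------------
# Study-level generation: 3 media x 2 charges x 3 sizes, mixtures per cell
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StudyDesign:
    """Mixture design of a synthetic tracking study.

    ``mixtures`` maps each medium to a list of ``(weight, SimulationConfig)``
    components; weights must sum to 1 per medium.  The per-component D is
    scaled by ``reference_size_nm / size`` (Stokes-Einstein: D ~ 1/radius)
    when the study spans several particle sizes.
    """

    mixtures: dict
    media: tuple = MEDIA
    charges: tuple = ("negative",)
    sizes_nm: tuple = (1000,)
    n_per_cell: int = 60
    n_frames: int = 100
    dt: float = 1.0
    loc_noise_sigma: float = 0.02
    reference_size_nm: int = 1000

    def __post_init__(self):
        for medium in self.media:
            if medium not in self.mixtures:
                raise ConfigError(f"no mixture defined for medium {medium!r}")
            weights = [w for w, _ in self.mixtures[medium]]
            if abs(sum(weights) - 1.0) > 1e-9:
                raise ConfigError(
                    f"mixture weights for {medium!r} sum to {sum(weights)}, not 1")


def default_study_design(kind: str = "heterogeneous", **overrides) -> StudyDesign:
    """Canned study designs.

    ``heterogeneous`` (default) emulates the composition of real mucus
    tracking data: every medium is a mixture of immobile, subdiffusive
    (fBm) and diffusive populations whose weights and parameters differ
    between media, so class distributions overlap.  ``disjoint`` gives
    each medium a single Brownian population with diffusivities separated
    by two orders of magnitude (0.001 / 0.1 / 10 um^2/s) - trivially
    separable.  ``identical`` gives all media the same Brownian
    population - classification is at chance.
    """
    base = dict(n_frames=100, dt=1.0)
    if kind == "heterogeneous":
        # Mixture weights emulate tracking data in mucus: mostly immobile
        # or subdiffusive populations whose proportions and mobility
        # differ between media; per-trajectory lognormal dispersion of D
        # (D_sigma) models the continuous spread of local diffusivities a
        # heterogeneous hydrogel presents.
        het = dict(base, D_sigma=0.3)
        mixtures = {
            # unimodal mobile population of intermediate mobility
            "PNCM": [
                (0.35, SimulationConfig(model="immobile", **base)),
                (0.45, SimulationConfig(model="fbm", D=0.12, hurst_H=0.35, **het)),
                (0.20, SimulationConfig(model="brownian", D=0.15, **het)),
            ],
            # bimodal mobile population flanking PNCM's mobility
            "PACM-HEC": [
                (0.30, SimulationConfig(model="immobile", **base)),
                (0.25, SimulationConfig(model="fbm", D=0.03, hurst_H=0.30, **het)),
                (0.25, SimulationConfig(model="fbm", D=0.45, hurst_H=0.40, **het)),
                (0.20, SimulationConfig(model="brownian", D=0.60, **het)),
            ],
            # most immobile/confined medium
            "PACM-PAA": [
                (0.45, SimulationConfig(model="immobile", **base)),
                (0.35, SimulationConfig(model="fbm", D=0.05, hurst_H=0.25, **het)),
                (0.20, SimulationConfig(model="confined", D=0.20,
                                        confinement_radius=0.30, **het)),
            ],
        }
    elif kind == "disjoint":
        mixtures = {
            medium: [(1.0, SimulationConfig(model="brownian", D=D, **base))]
            for medium, D in zip(MEDIA, (0.001, 0.1, 10.0))
        }
    elif kind == "identical":
        mixtures = {
            medium: [(1.0, SimulationConfig(model="brownian", D=0.1, **base))]
            for medium in MEDIA
        }
    else:
        raise ConfigError(f"unknown design kind {kind!r}")
    return StudyDesign(mixtures=mixtures, **overrides)


def load_study_design(path) -> StudyDesign:
    """Read a StudyDesign from a YAML file.

    Schema: a ``media`` mapping of medium name to a list of mixture
    components (each a mapping with ``weight``, ``model`` and any
    SimulationConfig parameter), plus optional top-level StudyDesign
    fields (charges, sizes_nm, n_per_cell, n_frames, dt,
    loc_noise_sigma, reference_size_nm).
    """
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "media" not in raw:
        raise ConfigError("study config must be a mapping with a 'media' key")
    mixtures = {}
    for medium, components in raw["media"].items():
        comps = []
        for comp in components:
            comp = dict(comp)
            weight = comp.pop("weight")
            comps.append((float(weight), SimulationConfig(**comp)))
        mixtures[medium] = comps
    fields = {k: (tuple(v) if isinstance(v, list) else v)
              for k, v in raw.items() if k != "media"}
    return StudyDesign(mixtures=mixtures, media=tuple(raw["media"]), **fields)


def build_synthetic_study(design: StudyDesign, seed: int = 0):
    """Generate a labeled study spanning media x charges x sizes.

    Returns ``(trajectories, labels)``: labels is a DataFrame with one row
    per trajectory (particle_id, medium, charge, nominal_diameter, model).
    Every (medium, charge, size) cell holds ``design.n_per_cell``
    trajectories drawn from the medium's mixture; component diffusivities
    are rescaled by reference_size_nm / size.
    """
    rng = np.random.default_rng(seed)
    trajectories, rows = [], []
    pid = 0
    for medium in design.media:
        components = design.mixtures[medium]
        weights = np.array([w for w, _ in components])
        for charge in design.charges:
            if charge not in CHARGES:
                raise ConfigError(f"unknown charge {charge!r}")
            for size in design.sizes_nm:
                if size not in SIZES_NM:
                    raise ConfigError(f"unknown size {size!r}")
                scale = design.reference_size_nm / size
                picks = rng.choice(len(components), size=design.n_per_cell, p=weights)
                for c in picks:
                    comp = components[c][1]
                    cfg = replace(
                        comp,
                        n_trajectories=1,
                        n_frames=design.n_frames,
                        dt=design.dt,
                        D=comp.D * scale,
                        state_D=tuple(d * scale for d in comp.state_D),
                        loc_noise_sigma=design.loc_noise_sigma,
                    )
                    pos, _ = _positions(_disperse(cfg, rng), rng)
                    if cfg.loc_noise_sigma > 0:
                        pos = pos + rng.standard_normal(pos.shape) * cfg.loc_noise_sigma
                    trajectories.append(Trajectory(
                        particle_id=pid, frames=np.arange(cfg.n_frames),
                        x=pos[:, 0], y=pos[:, 1], dt=cfg.dt))
                    rows.append({"particle_id": pid, "medium": medium,
                                 "charge": charge, "nominal_diameter": size,
                                 "model": comp.model})
                    pid += 1
    return trajectories, pd.DataFrame(rows)
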