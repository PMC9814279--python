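"""Synthetic inputs with known ground truth for every analysis stage.

Each generator emulates one class of input the pipeline consumes and is
exactly reproducible from its seed:

* an Ornstein-Uhlenbeck force series with prescribed variance and
  correlation time (analytic oracle for the Green-Kubo integral),
* spherical-cap droplet samples with a prescribed contact angle and a
  tanh-smoothed liquid-vapor boundary (oracle for the interface fit),
* Metropolis-sampled rigid single-water poses in the first layer over a
  surface energy landscape (exercises the energy-map binning exactly as
  MD frames would; water-water forces are deliberately omitted),
* linear lambda-(Delta E_micro)^2 datasets with multiplicative noise.

The single-molecule Monte Carlo is a physical simplification: it tests
layer selection, binning and Boltzmann consistency of maps, not absolute
friction values.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter
from scipy.spatial.transform import Rotation

from . import constants as const
from .energymap import SPCE, WaterConfig, WaterModel, pair_energy
from .greenkubo import ForceSeries
from .model import LambdaE2Dataset
from .surfaces import Surface

__all__ = [
    "OUSpec",
    "CapSpec",
    "LayerMCSpec",
    "MCResult",
    "gen_ou_force",
    "gen_droplet",
    "gen_first_layer",
    "gen_lambda_dataset",
]

#: Default in-plane surface area, nm^2 (6.395 nm x 6.816 nm footprint).
DEFAULT_AREA = 6.395 * 6.816

#: Ambient water number density, nm^-3.
WATER_NUMBER_DENSITY = 33.4


@dataclass
class OUSpec:
    """Ornstein-Uhlenbeck force-series parameters.

    The generated process is stationary and Gaussian with
    <F(t) F(0)> = sigma2 * exp(-t / tau).
    """

    sigma2: float              # (kJ mol^-1 nm^-1)^2
    tau: float                 # ps
    dt: float                  # ps
    n: int
    seed: int | None = None
    components: int = 1
    area: float = DEFAULT_AREA       # nm^2
    temperature: float = 300.0       # K

    def __post_init__(self):
        if min(self.sigma2, self.tau, self.dt) <= 0 or self.n < 2:
            raise ValueError("sigma2, tau, dt must be > 0 and n >= 2")
        if self.components not in (1, 2):
            raise ValueError("components must be 1 or 2")
        if self.dt > self.tau / 10.0:
            warnings.warn(
                f"dt = {self.dt} ps resolves the correlation time tau = "
                f"{self.tau} ps poorly (dt > tau/10)", stacklevel=2)


def gen_ou_force(spec: OUSpec) -> ForceSeries:
    """Sample an OU force series via the exact discrete update.

    x_{k+1} = a x_k + sqrt(sigma2 (1 - a^2)) w_k with a = exp(-dt/tau)
    and a stationary initial draw, so every finite sample is exactly
    stationary with the exponential ACF above.
    """
    rng = np.random.default_rng(spec.seed)
    a = math.exp(-spec.dt / spec.tau)
    c = math.sqrt(spec.sigma2 * (1.0 - a * a))
    cols = []
    for _ in range(spec.components):
        x0 = math.sqrt(spec.sigma2) * rng.standard_normal()
        w = rng.standard_normal(spec.n)
        x, _ = lfilter([1.0], [1.0, -a], c * w, zi=[a * x0])
        cols.append(x)
    values = cols[0] if spec.components == 1 else np.column_stack(cols)
    return ForceSeries(spec.dt, values, spec.area, spec.temperature,
                       {"generator": "ou", "sigma2": spec.sigma2,
                        "tau": spec.tau, "seed": spec.seed})


@dataclass
class CapSpec:
    """Spherical-cap droplet sampling parameters.

    ``r_sphere`` is the sphere radius; when left ``None`` it is chosen so
    the cap rises at least 2 nm above the surface (so the interface fit
    has room above its wall-exclusion height).  ``noise`` is the standard
    deviation of isotropic positional jitter as a fraction of the sphere
    radius.  Each of the ``n_frames`` snapshots draws a Poisson number of
    molecules matching ``rho_bulk``.
    """

    theta_true: float               # degrees
    r_sphere: float | None = None   # nm
    rho_bulk: float = WATER_NUMBER_DENSITY
    width: float = 0.3              # tanh interface width, nm
    n_frames: int = 50
    noise: float = 0.0
    seed: int | None = None

    def __post_init__(self):
        if not 0.0 < self.theta_true < 180.0:
            raise ValueError("theta_true must lie in (0, 180) degrees")
        if self.r_sphere is not None and self.r_sphere <= 0:
            raise ValueError("r_sphere must be > 0")
        if self.rho_bulk <= 0 or self.width <= 0 or self.n_frames < 1:
            raise ValueError("rho_bulk, width must be > 0 and n_frames >= 1")

    @property
    def radius(self) -> float:
        if self.r_sphere is not None:
            return self.r_sphere
        h_over_r = 1.0 - math.cos(math.radians(self.theta_true))
        return max(2.5, 2.0 / h_over_r)


def gen_droplet(spec: CapSpec) -> list:
    """Sample droplet frames: points uniform inside a spherical cap.

    The cap of contact angle ``theta_true`` sits on the z = 0 plane
    (sphere center at z0 = -R cos theta).  Acceptance decays as
    0.5 (1 - tanh((d - R)/width)) in the distance d from the sphere
    center, producing a smooth liquid-vapor profile whose half-density
    surface is the sphere itself.  Returns a list of (N, 3) arrays.
    """
    rng = np.random.default_rng(spec.seed)
    theta = math.radians(spec.theta_true)
    radius = spec.radius
    z0 = -radius * math.cos(theta)
    z_top = z0 + radius
    pad = 3.0 * spec.width
    r_box = (radius if spec.theta_true > 90.0
             else radius * math.sin(theta)) + pad
    z_box = z_top + pad
    vol_box = math.pi * r_box * r_box * z_box

    frames = []
    for _ in range(spec.n_frames):
        n = rng.poisson(spec.rho_bulk * vol_box)
        u = rng.random(n)
        phi = rng.random(n) * 2.0 * math.pi
        r = r_box * np.sqrt(u)
        pts = np.column_stack([r * np.cos(phi), r * np.sin(phi),
                               rng.random(n) * z_box])
        d = np.linalg.norm(pts - np.array([0.0, 0.0, z0]), axis=1)
        accept = rng.random(n) < 0.5 * (1.0 - np.tanh((d - radius) / spec.width))
        pts = pts[accept]
        if spec.noise > 0:
            pts = pts + rng.normal(0.0, spec.noise * radius, pts.shape)
            pts[:, 2] = np.abs(pts[:, 2])  # reflect at the wall
        frames.append(pts)
    return frames


@dataclass
class LayerMCSpec:
    """Single-molecule Metropolis sampling of first-layer water poses."""

    surface: Surface
    temperature: float = 300.0       # K; np.inf gives unit acceptance
    n_molecules: int = 8
    n_sweeps: int = 200
    step_translation: float = 0.05   # nm
    step_rotation_deg: float = 30.0
    thickness: float = 0.50          # nm
    cutoff: float = 1.0              # nm
    seed: int | None = None
    model: WaterModel = field(default_factory=lambda: SPCE)

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")
        if self.step_translation <= 0 or self.step_rotation_deg <= 0:
            raise ValueError("step sizes must be > 0")
        if self.n_molecules < 1 or self.n_sweeps < 1:
            raise ValueError("n_molecules and n_sweeps must be >= 1")


@dataclass
class MCResult:
    """Frames plus diagnostics from the layer Monte Carlo."""

    frames: list                 # list of frames, each a list of WaterConfig
    acceptance_rate: float
    energies: np.ndarray         # (n_sweeps,) mean energy per sweep, kJ/mol
    spec: LayerMCSpec


def gen_first_layer(spec: LayerMCSpec) -> MCResult:
    """Metropolis sampling of non-interacting rigid waters in the layer.

    Each molecule performs one translation + rotation attempt per sweep
    on the solid-water energy alone; moves leaving the half-open layer
    (z_plane, z_plane + thickness] are rejected.  At infinite temperature
    every in-layer move is accepted and the (x, y) marginal is uniform.
    """
    rng = np.random.default_rng(spec.seed)
    surf = spec.surface
    lx, ly = surf.rect_lengths
    z0 = surf.z_plane
    beta = 0.0 if math.isinf(spec.temperature) else 1.0 / (
        const.KB * spec.temperature)

    def energy(water):
        return pair_energy(water, surf, spec.cutoff, model=spec.model).total

    poses = []
    for _ in range(spec.n_molecules):
        o = np.array([rng.random() * lx, rng.random() * ly,
                      z0 + spec.thickness * (1.0 - rng.random())])
        rot = Rotation.random(rng=rng)
        w = WaterConfig.from_pose(o, rot, spec.model)
        poses.append([o, rot, w, energy(w)])

    frames = []
    energies = np.empty(spec.n_sweeps)
    n_accept = 0
    step_rot = math.radians(spec.step_rotation_deg)
    for sweep in range(spec.n_sweeps):
        accepted_this_sweep = 0
        for pose in poses:
            o, rot, w, e = pose
            o_new = o + rng.normal(0.0, spec.step_translation, 3)
            o_new[0] %= lx
            o_new[1] %= ly
            if not z0 < o_new[2] <= z0 + spec.thickness:
                continue
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            rot_new = Rotation.from_rotvec(
                axis * rng.normal(0.0, step_rot)) * rot
            w_new = WaterConfig.from_pose(o_new, rot_new, spec.model)
            e_new = energy(w_new)
            if beta == 0.0 or math.log(rng.random() + 1e-300) < -beta * (e_new - e):
                pose[0], pose[1], pose[2], pose[3] = o_new, rot_new, w_new, e_new
                n_accept += 1
                accepted_this_sweep += 1
        if accepted_this_sweep == 0:
            warnings.warn(f"sweep {sweep}: no move accepted", stacklevel=2)
        frames.append([pose[2] for pose in poses])
        energies[sweep] = float(np.mean([pose[3] for pose in poses]))
    rate = n_accept / (spec.n_sweeps * spec.n_molecules)
    return MCResult(frames, rate, energies, spec)


def gen_lambda_dataset(zeta_true: float, var_e, noise: float = 0.0,
                       seed: int | None = None, kind: str = "hexagonal",
                       q=None) -> LambdaE2Dataset:
    """Linear lambda = zeta_true * var_E records with multiplicative noise.

    lambda_i = zeta_true * varE_i * (1 + noise * eps_i), eps ~ N(0, 1).
    """
    var_e = np.asarray(var_e, dtype=float)
    if np.any(var_e < 0):
        raise ValueError("var_e must be >= 0")
    rng = np.random.default_rng(seed)
    factor = 1.0 + noise * rng.standard_normal(len(var_e)) if noise > 0 else 1.0
    lam = zeta_true * var_e * factor
    n = len(var_e)
    if q is None:
        q = np.full(n, np.nan)
    return LambdaE2Dataset(
        np.array([f"synthetic-{i}" for i in range(n)]),
        np.asarray(q, dtype=float), var_e, lam, np.full(n, kind))
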