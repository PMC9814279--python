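"""Water-surface energy landscapes on fine in-plane grids.

The microscopic interaction energy E_micro of a first-layer water molecule
with all surface atoms (Lennard-Jones + truncated Coulomb, 1.0 nm cutoff)
is accumulated on a grid of small square cells (default edge 0.05 nm, cell
area 0.25 A^2).  The variance of the resulting map over the surface,
(Delta E_micro)^2 = <(E_micro - <E_micro>)^2>, quantifies the corrugation
of the energy landscape: a smooth map means little resistance to lateral
water motion, a fragmented map means high interfacial friction.

Electrostatics use a minimum-image direct sum over periodic images within
the cutoff (the overall surface neutrality keeps the truncation error
small); this is a deliberate desk-scale approximation to mesh Ewald
summation.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from . import constants as const
from .surfaces import Surface

__all__ = [
    "WaterModel",
    "WaterConfig",
    "PairEnergy",
    "EnergyGrid",
    "MapStats",
    "GridError",
    "SPCE",
    "pair_energy",
    "select_first_layer",
    "accumulate_map",
    "probe_map",
    "map_stats",
    "interface_energy_density",
    "default_orientations",
]

#: Hard-core distance below which a water-site/surface-atom pair is
#: flagged as an overlap (nm).
OVERLAP_DISTANCE = 0.05


class GridError(ValueError):
    """Raised for grids that do not tile the periodic surface cell."""


@dataclass(frozen=True)
class WaterModel:
    """Rigid three-site water model; SPC/E by default (LJ on oxygen only)."""

    q_o: float = const.SPCE_QO
    q_h: float = const.SPCE_QH
    r_oh: float = const.SPCE_OH
    angle_deg: float = const.SPCE_ANGLE
    o_sigma: float = const.SPCE_O_SIGMA
    o_epsilon: float = const.SPCE_O_EPSILON

    def __post_init__(self):
        if abs(self.q_o + 2.0 * self.q_h) > 1e-12:
            raise ValueError("water model must be neutral: q_O + 2 q_H = 0")

    @property
    def site_charges(self) -> np.ndarray:
        return np.array([self.q_o, self.q_h, self.q_h])

    def reference_sites(self) -> np.ndarray:
        """Site offsets (O, H, H) with O at the origin and the dipole along +z."""
        half = math.radians(self.angle_deg / 2.0)
        s, c = math.sin(half), math.cos(half)
        return np.array([
            [0.0, 0.0, 0.0],
            [self.r_oh * s, 0.0, self.r_oh * c],
            [-self.r_oh * s, 0.0, self.r_oh * c],
        ])


#: Module-level SPC/E instance used as the default everywhere.
SPCE = WaterModel()


@dataclass(frozen=True)
class WaterConfig:
    """A rigid water pose: O and two H positions in nm."""

    o: tuple
    h1: tuple
    h2: tuple

    def __post_init__(self):
        for name in ("o", "h1", "h2"):
            object.__setattr__(self, name,
                               tuple(float(x) for x in getattr(self, name)))

    @classmethod
    def from_pose(cls, o_position, rotation: Rotation | None = None,
                  model: WaterModel = SPCE) -> "WaterConfig":
        """Build a rigid water with O at ``o_position`` and given orientation."""
        ref = model.reference_sites()
        if rotation is not None:
            ref = rotation.apply(ref)
        sites = np.asarray(o_position, dtype=float) + ref
        return cls(tuple(sites[0]), tuple(sites[1]), tuple(sites[2]))

    def sites(self) -> np.ndarray:
        return np.array([self.o, self.h1, self.h2])

    def validate(self, model: WaterModel = SPCE,
                 tol_bond: float = 1e-6, tol_angle: float = 1e-4) -> None:
        """Check the rigid-geometry invariants (bond lengths and angle)."""
        s = self.sites()
        v1, v2 = s[1] - s[0], s[2] - s[0]
        r1, r2 = np.linalg.norm(v1), np.linalg.norm(v2)
        if abs(r1 - model.r_oh) > tol_bond or abs(r2 - model.r_oh) > tol_bond:
            raise ValueError("O-H bond length violates the rigid geometry")
        ang = math.degrees(math.acos(np.clip(v1 @ v2 / (r1 * r2), -1, 1)))
        if abs(ang - model.angle_deg) > tol_angle:
            raise ValueError("H-O-H angle violates the rigid geometry")


@dataclass(frozen=True)
class PairEnergy:
    """Water-surface interaction energy split into LJ and Coulomb parts."""

    lj: float
    coulomb: float
    overlap: bool = False

    @property
    def total(self) -> float:
        return self.lj + self.coulomb


# ---------------------------------------------------------------------
# Pairwise energy core
# ---------------------------------------------------------------------

def _expanded_atoms(surface: Surface, cutoff: float):
    """Surface atoms replicated over the periodic images needed for ``cutoff``.

    The image range covers any water site whose O lies inside the cell
    (molecular extent < 0.2 nm is padded for).
    """
    key = ("images", round(float(cutoff), 12))
    cached = surface._cache.get(key)
    if cached is not None:
        return cached
    lx, ly = surface.rect_lengths
    nix = int(math.ceil((cutoff + 0.2) / lx)) + 1
    niy = int(math.ceil((cutoff + 0.2) / ly)) + 1
    shifts = np.array([(i * lx, j * ly, 0.0)
                       for i in range(-nix, nix + 1)
                       for j in range(-niy, niy + 1)])
    pos = (surface.positions[None, :, :] + shifts[:, None, :]).reshape(-1, 3)
    rep = len(shifts)
    out = (pos,
           np.tile(surface.charges, rep),
           np.tile(surface.lj_epsilons, rep),
           np.tile(surface.lj_sigmas, rep))
    surface._cache[key] = out
    return out


def _combine_lj(model: WaterModel, eps: np.ndarray, sig: np.ndarray,
                combining: str):
    eps_c = np.sqrt(model.o_epsilon * eps)
    if combining in ("lorentz", "lorentz-berthelot"):
        sig_c = 0.5 * (model.o_sigma + sig)
    elif combining == "geometric":
        sig_c = np.sqrt(model.o_sigma * sig)
    else:
        raise ValueError(f"unknown LJ combining rule {combining!r}")
    return eps_c, sig_c


def _interaction_batch(sites: np.ndarray, surface: Surface, cutoff: float,
                       combining: str, model: WaterModel,
                       chunk: int = 512):
    """LJ/Coulomb energies for a batch of waters.

    Parameters
    ----------
    sites:
        Array of shape (W, 3, 3): W waters x (O, H, H) positions, nm.
        Molecules are wrapped into the cell by their O position.

    Returns
    -------
    (lj, coulomb, overlap) arrays of shape (W,).
    """
    sites = np.asarray(sites, dtype=float)
    if sites.ndim == 2:
        sites = sites[None]
    lx, ly = surface.rect_lengths
    # wrap whole molecules by O so every site is within one cell + 0.2 nm
    shift = np.zeros_like(sites)
    shift[:, :, 0] = np.floor(sites[:, 0:1, 0] / lx) * lx
    shift[:, :, 1] = np.floor(sites[:, 0:1, 1] / ly) * ly
    sites = sites - shift

    apos, aq, aeps, asig = _expanded_atoms(surface, cutoff)
    eps_c, sig_c = _combine_lj(model, aeps, asig, combining)
    qsite = model.site_charges

    n = sites.shape[0]
    lj = np.empty(n)
    coul = np.empty(n)
    overlap = np.empty(n, dtype=bool)
    for start in range(0, n, chunk):
        blk = sites[start:start + chunk]           # (w, 3, 3)
        d = blk[:, :, None, :] - apos[None, None, :, :]
        r = np.sqrt(np.einsum("wsmx,wsmx->wsm", d, d))
        # charge-group truncation: the whole (neutral) water interacts
        # with a surface atom iff the O-atom distance is within the
        # cutoff, so truncation never cuts through a molecule
        within = (r[:, 0:1, :] <= cutoff) & np.ones(
            (1, r.shape[1], 1), dtype=bool)
        overlap[start:start + chunk] = (r < OVERLAP_DISTANCE).any(axis=(1, 2))
        with np.errstate(divide="ignore", invalid="ignore"):
            inv_r = np.where(within, 1.0 / r, 0.0)
        coul[start:start + chunk] = const.KE * np.einsum(
            "s,m,wsm->w", qsite, aq, inv_r)
        # LJ acts on the O site only (site 0); surface H atoms do carry LJ.
        sr6 = np.where(within[:, 0, :],
                       (sig_c[None, :] * inv_r[:, 0, :]) ** 6, 0.0)
        lj[start:start + chunk] = np.einsum(
            "m,wm->w", 4.0 * eps_c, sr6 * sr6 - sr6)
    return lj, coul, overlap


def pair_energy(water: WaterConfig, surface: Surface, cutoff: float = 1.0,
                combining: str = "lorentz", model: WaterModel = SPCE) -> PairEnergy:
    """Interaction energy of one water with all surface atoms within ``cutoff``.

    LJ uses the chosen combining rule between the water oxygen and each
    surface atom; Coulomb sums k_e q_i q_j / r over every water-site /
    surface-atom pair (minimum-image over periodic in-plane images).
    The cutoff is applied per charge group: all three water sites
    interact with a surface atom iff the O-atom distance is within the
    cutoff, which keeps the truncated energy a smooth function of the
    cutoff (only neutral-molecule/monopole terms enter or leave).
    A pair closer than 0.05 nm flags ``overlap`` but the energy is still
    returned.
    """
    lj, coul, overlap = _interaction_batch(water.sites()[None], surface,
                                           cutoff, combining, model)
    return PairEnergy(float(lj[0]), float(coul[0]), bool(overlap[0]))


def select_first_layer(frame, surface: Surface,
                       thickness: float = 0.50) -> list:
    """Waters whose O height lies in the half-open layer (z_plane, z_plane + t].

    The upper bound is closed, so an O exactly at the layer top is included.
    """
    z0 = surface.z_plane
    return [w for w in frame if z0 < w.o[2] <= z0 + thickness]


# ---------------------------------------------------------------------
# Grids
# ---------------------------------------------------------------------

def _axis_cells(length: float, edge: float, snap: bool) -> tuple:
    n = length / edge
    n_round = max(1, int(round(n)))
    if abs(n - n_round) > 1e-6 * max(1.0, n):
        if snap:
            return n_round, length / n_round
        raise GridError(
            f"grid edge {edge} nm is not commensurate with the cell length "
            f"{length} nm; nearest commensurate edge is {length / n_round:.9g} nm")
    return n_round, length / n_round


def _grid_geometry(surface: Surface, edge, snap: bool):
    lx, ly = surface.rect_lengths
    ex, ey = (edge, edge) if np.isscalar(edge) else edge
    nx, ex = _axis_cells(lx, ex, snap)
    ny, ey = _axis_cells(ly, ey, snap)
    return nx, ny, ex, ey


@dataclass
class EnergyGrid:
    """Per-cell mean water-surface energies on a periodic in-plane grid.

    ``mean_total``/``mean_lj``/``mean_coulomb`` hold NaN where a cell has
    no observations; use the masked-array properties for statistics.
    """

    edges: tuple          # (ex, ey) actual cell edges, nm
    cell_lengths: tuple   # (Lx, Ly) of the periodic surface cell, nm
    mean_total: np.ndarray
    mean_lj: np.ndarray
    mean_coulomb: np.ndarray
    counts: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple:
        return self.mean_total.shape

    @property
    def mask(self) -> np.ndarray:
        return self.counts == 0

    @property
    def values(self) -> np.ma.MaskedArray:
        return np.ma.masked_array(self.mean_total, self.mask)

    @property
    def lj(self) -> np.ma.MaskedArray:
        return np.ma.masked_array(self.mean_lj, self.mask)

    @property
    def coulomb(self) -> np.ma.MaskedArray:
        return np.ma.masked_array(self.mean_coulomb, self.mask)

    @property
    def x_centers(self) -> np.ndarray:
        return (np.arange(self.shape[0]) + 0.5) * self.edges[0]

    @property
    def y_centers(self) -> np.ndarray:
        return (np.arange(self.shape[1]) + 0.5) * self.edges[1]

    def to_csv(self, path) -> None:
        """Export the total-energy map as a CSV matrix (rows = x cells)."""
        import pandas as pd
        pd.DataFrame(self.mean_total).to_csv(path, index=False, header=False)


@dataclass
class MapStats:
    """Summary statistics of an energy map."""

    mean_e: float        # <E_micro>, kJ/mol
    var_e: float         # (Delta E_micro)^2, (kJ/mol)^2
    hist_counts: np.ndarray
    hist_edges: np.ndarray
    n_cells: int
    weighting: str = "cell"

    @property
    def std_e(self) -> float:
        """Delta E_micro, kJ/mol."""
        return math.sqrt(self.var_e)


def accumulate_map(trajectory, surface: Surface, edge=0.05,
                   thickness: float = 0.50, cutoff: float = 1.0,
                   snap: bool = False, per_molecule: bool = False,
                   combining: str = "lorentz",
                   model: WaterModel = SPCE) -> EnergyGrid:
    """Accumulate E_micro over first-layer waters of a trajectory.

    Each first-layer water in each frame contributes one observation:
    its pair energy with the whole surface, binned by the in-plane O
    position.  Cell values are observation averages; empty cells stay
    masked.  With ``per_molecule=True`` the energies and positions of
    each molecule index are time-averaged first and contribute a single
    observation (frames must then list molecules in a consistent order).
    """
    nx, ny, ex, ey = _grid_geometry(surface, edge, snap)
    lx, ly = surface.rect_lengths

    obs_xy = []
    obs_e = []   # rows (lj, coul)
    mol_acc: dict = {}
    for frame in trajectory:
        layer = [(i, w) for i, w in enumerate(frame)
                 if surface.z_plane < w.o[2] <= surface.z_plane + thickness]
        if not layer:
            continue
        sites = np.stack([w.sites() for _, w in layer])
        lj, coul, _ = _interaction_batch(sites, surface, cutoff, combining, model)
        for (idx, w), elj, ecoul in zip(layer, lj, coul):
            if per_molecule:
                acc = mol_acc.setdefault(idx, [0.0, 0.0, 0.0, 0.0, 0])
                acc[0] += w.o[0]
                acc[1] += w.o[1]
                acc[2] += elj
                acc[3] += ecoul
                acc[4] += 1
            else:
                obs_xy.append((w.o[0], w.o[1]))
                obs_e.append((elj, ecoul))
    if per_molecule:
        for acc in mol_acc.values():
            n = acc[4]
            obs_xy.append((acc[0] / n, acc[1] / n))
            obs_e.append((acc[2] / n, acc[3] / n))

    sum_lj = np.zeros((nx, ny))
    sum_coul = np.zeros((nx, ny))
    counts = np.zeros((nx, ny), dtype=int)
    for (x, y), (elj, ecoul) in zip(obs_xy, obs_e):
        ix = int((x % lx) / ex) % nx
        iy = int((y % ly) / ey) % ny
        sum_lj[ix, iy] += elj
        sum_coul[ix, iy] += ecoul
        counts[ix, iy] += 1
    with np.errstate(invalid="ignore"):
        mean_lj = np.where(counts > 0, sum_lj / np.maximum(counts, 1), np.nan)
        mean_coul = np.where(counts > 0, sum_coul / np.maximum(counts, 1), np.nan)
    return EnergyGrid((ex, ey), (lx, ly), mean_lj + mean_coul,
                      mean_lj, mean_coul, counts,
                      {"source": "trajectory", "thickness": thickness,
                       "cutoff": cutoff, "per_molecule": per_molecule})


def default_orientations(n: int = 32, seed: int = 20250925) -> Rotation:
    """A reproducible set of ``n`` orientations, uniform over rotations."""
    if n < 1:
        raise ValueError("need at least one orientation")
    return Rotation.random(n, rng=np.random.default_rng(seed))


def probe_map(surface: Surface, z_probe: float, orientations=32,
              temperature: float = 300.0, edge=0.05, cutoff: float = 1.0,
              weighting: str = "boltzmann", snap: bool = False,
              combining: str = "lorentz",
              model: WaterModel = SPCE) -> EnergyGrid:
    """Deterministic energy map probed on grid-cell centers.

    For every grid cell a rigid water is placed with its O at the cell
    center and height ``z_probe``, and the pair energy is averaged over an
    orientation quadrature: Boltzmann-weighted at ``temperature`` (default)
    or plain-uniform (``weighting="uniform"``).  The uniform average keeps
    the Coulomb component exactly linear in the decoration charge q, which
    the q^2-scaling checks exploit.
    """
    if isinstance(orientations, Rotation):
        rot_list = [orientations] if orientations.single else list(orientations)
    else:
        rot_list = list(default_orientations(int(orientations)))
    n_rot = len(rot_list)
    if n_rot == 0:
        raise ValueError("empty orientation set")
    if weighting not in ("boltzmann", "uniform"):
        raise ValueError(f"unknown weighting {weighting!r}")

    nx, ny, ex, ey = _grid_geometry(surface, edge, snap)
    lx, ly = surface.rect_lengths
    xs = (np.arange(nx) + 0.5) * ex
    ys = (np.arange(ny) + 0.5) * ey
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    centers = np.column_stack([
        gx.ravel(), gy.ravel(),
        np.full(nx * ny, surface.z_plane + z_probe)])

    ref = model.reference_sites()
    e_lj = np.empty((n_rot, nx * ny))
    e_coul = np.empty((n_rot, nx * ny))
    for k in range(n_rot):
        offsets = rot_list[k].apply(ref)
        sites = centers[:, None, :] + offsets[None, :, :]
        lj, coul, _ = _interaction_batch(sites, surface, cutoff, combining, model)
        e_lj[k] = lj
        e_coul[k] = coul

    if weighting == "uniform":
        w = np.full((n_rot, nx * ny), 1.0 / n_rot)
    else:
        total = e_lj + e_coul
        beta = 1.0 / (const.KB * temperature)
        logw = -beta * (total - total.min(axis=0, keepdims=True))
        w = np.exp(logw)
        w /= w.sum(axis=0, keepdims=True)

    mean_lj = (w * e_lj).sum(axis=0).reshape(nx, ny)
    mean_coul = (w * e_coul).sum(axis=0).reshape(nx, ny)
    counts = np.full((nx, ny), n_rot, dtype=int)
    return EnergyGrid((ex, ey), (lx, ly), mean_lj + mean_coul,
                      mean_lj, mean_coul, counts,
                      {"source": "probe", "z_probe": z_probe,
                       "weighting": weighting, "temperature": temperature,
                       "n_orientations": n_rot, "cutoff": cutoff})


def map_stats(grid: EnergyGrid, weighting: str = "cell",
              bin_width: float = 0.05, component: str = "total") -> MapStats:
    """Mean, variance and histogram of an energy map.

    ``weighting="cell"`` (default) treats every unmasked cell equally,
    matching a standard deviation taken over the map itself;
    ``"occupancy"`` weights cells by their observation counts.
    ``component`` selects "total", "lj" or "coulomb".
    """
    if weighting not in ("cell", "occupancy"):
        raise ValueError(f"unknown weighting {weighting!r}")
    arr = {"total": grid.values, "lj": grid.lj, "coulomb": grid.coulomb}[component]
    good = ~grid.mask
    vals = np.asarray(arr[good], dtype=float)
    if vals.size < 2:
        raise ValueError("map statistics need at least 2 unmasked cells")
    weights = grid.counts[good].astype(float) if weighting == "occupancy" else None
    mean = float(np.average(vals, weights=weights))
    var = float(np.average((vals - mean) ** 2, weights=weights))
    lo = math.floor(vals.min() / bin_width) * bin_width
    hi = math.ceil(vals.max() / bin_width) * bin_width
    nbins = max(1, int(round((hi - lo) / bin_width)))
    counts, edges = np.histogram(vals, bins=nbins, range=(lo, lo + nbins * bin_width),
                                 weights=weights)
    return MapStats(mean, var, counts, edges, int(vals.size), weighting)


def interface_energy_density(trajectory, surface: Surface,
                             cutoff: float = 1.0, combining: str = "lorentz",
                             model: WaterModel = SPCE) -> float:
    """Frame-averaged total solid-water energy per unit area, kJ mol^-1 nm^-2.

    Unlike :func:`accumulate_map`, every water in each frame contributes,
    not only the first layer.
    """
    area = surface.area
    if area <= 0:
        raise ValueError("surface cell has zero area")
    totals = []
    for frame in trajectory:
        if not frame:
            totals.append(0.0)
            continue
        sites = np.stack([w.sites() for w in frame])
        lj, coul, _ = _interaction_batch(sites, surface, cutoff, combining, model)
        totals.append(float(lj.sum() + coul.sum()))
    if not totals:
        raise ValueError("empty trajectory")
    return float(np.mean(totals)) / area
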