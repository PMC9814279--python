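"""Contact angles from droplet density fields, and the wetting-friction link.

A sessile nanodroplet is reduced to a cylindrical (r, z) number-density
histogram around its symmetry axis.  The liquid-vapor interface is the
locus where the density falls through half the bulk value; a circle is
fitted to those points (excluding the structured region near the wall)
and the contact angle theta is the angle between the circle tangent at
the contact height and the surface plane, measured through the liquid.

The theoretical relative friction implied by two contact angles follows
the quasi-universal relation lambda* ~ (1 + cos theta)^2 for water on
smooth surfaces.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "DensityField",
    "ContactAngleResult",
    "InterfaceError",
    "density_field",
    "extract_interface",
    "fit_contact_angle",
    "contact_angle_from_frames",
    "huang_relative_friction",
]


class InterfaceError(ValueError):
    """Raised when no liquid-vapor interface can be located or fitted."""


@dataclass
class DensityField:
    """Cylindrically binned water number density around a droplet axis."""

    r_edges: np.ndarray   # nm
    z_edges: np.ndarray   # nm
    density: np.ndarray   # (nz, nr), nm^-3
    axis: tuple           # (x0, y0) of the symmetry axis, nm
    n_frames: int = 1

    def __post_init__(self):
        if np.any(self.density < 0):
            raise ValueError("densities must be non-negative")

    @property
    def r_centers(self) -> np.ndarray:
        return 0.5 * (self.r_edges[:-1] + self.r_edges[1:])

    @property
    def z_centers(self) -> np.ndarray:
        return 0.5 * (self.z_edges[:-1] + self.z_edges[1:])


@dataclass
class ContactAngleResult:
    """A fitted liquid-vapor circle and the contact angle it implies."""

    theta: float          # degrees, through the liquid
    center: tuple         # (r_c, z_c) of the fitted circle, nm
    radius: float         # nm
    residual: float       # rms distance of points from the circle, nm
    n_interface_points: int
    z_exclude: float
    z_contact: float

    def __post_init__(self):
        if not 0.0 < self.theta < 180.0:
            raise ValueError(f"theta = {self.theta} deg outside (0, 180)")


def density_field(frames, dr: float = 0.1, dz: float = 0.05,
                  axis=None) -> DensityField:
    """Bin droplet frames into a cylindrical (r, z) number density.

    ``frames`` is a sequence of (N, 3) position arrays in nm (one per
    snapshot; N may vary).  The symmetry axis defaults to the mean of the
    per-frame in-plane centers of mass.
    """
    frames = [np.asarray(f, dtype=float).reshape(-1, 3) for f in frames]
    frames = [f for f in frames if len(f)]
    if not frames:
        raise ValueError("empty trajectory")
    if axis is None:
        coms = np.array([f[:, :2].mean(axis=0) for f in frames])
        axis = tuple(coms.mean(axis=0))

    allp = np.concatenate(frames)
    r = np.hypot(allp[:, 0] - axis[0], allp[:, 1] - axis[1])
    z = allp[:, 2]
    r_edges = np.arange(0.0, r.max() + 2 * dr, dr)
    z_lo = min(0.0, math.floor(z.min() / dz) * dz)
    z_edges = np.arange(z_lo, z.max() + 2 * dz, dz)
    counts, _, _ = np.histogram2d(z, r, bins=(z_edges, r_edges))
    shell = math.pi * (r_edges[1:] ** 2 - r_edges[:-1] ** 2)  # (nr,)
    vol = shell[None, :] * dz * len(frames)
    return DensityField(r_edges, z_edges, counts / vol, axis, len(frames))


def estimate_bulk_density(field: DensityField, margin: float = 0.9) -> float:
    """Bulk liquid density from bins deep inside the droplet, nm^-3.

    Two passes: a crude volume-weighted average over occupied bins first
    locates the half-density radius of each z row; the bulk value is then
    the volume-weighted mean of bins lying at least ``margin`` nm inside
    that radius (rows too narrow to hold such a core are skipped).  The
    margin keeps the smooth liquid-vapor tail out of the average.
    """
    dens = field.density
    occ = dens > 0
    if not occ.any():
        raise InterfaceError("density field is empty")
    rc = field.r_centers
    dr = rc[1] - rc[0] if len(rc) > 1 else 1.0
    vol_w = np.broadcast_to(rc, dens.shape)
    rho_crude = float(np.average(dens[occ], weights=vol_w[occ]))
    vals, wts = [], []
    for i in range(dens.shape[0]):
        r_cross = _row_crossing(rc, dens[i], 0.5 * rho_crude)
        if r_cross is None or r_cross < margin + 2 * dr:
            continue
        sel = rc < r_cross - margin
        vals.append(dens[i][sel])
        wts.append(rc[sel])
    if not vals:
        return rho_crude
    return float(np.average(np.concatenate(vals),
                            weights=np.concatenate(wts)))


def _row_crossing(rc, row, thr):
    """Outermost downward crossing of ``thr`` in one z row, or None."""
    above = row >= thr
    if not above.any():
        return None
    j = int(np.where(above)[0][-1])
    if j == len(row) - 1:
        # still above threshold at the outermost bin: no vapor side
        return None
    r0, r1 = rc[j], rc[j + 1]
    d0, d1 = row[j], row[j + 1]
    return r0 + (d0 - thr) / (d0 - d1) * (r1 - r0)


def extract_interface(field: DensityField, threshold_fraction: float = 0.5,
                      z_min: float | None = None,
                      rho_bulk: float | None = None,
                      min_plateau_fraction: float = 0.85) -> np.ndarray:
    """Locate the liquid-vapor interface as (r, z) points.

    For every z row the outermost downward crossing of
    ``threshold_fraction * rho_bulk`` is found by linear interpolation
    between radial bins.  Rows whose peak density stays below
    ``min_plateau_fraction * rho_bulk`` are skipped: they hold no liquid
    interior (cap apex, stray vapor) and their crossings do not track the
    isodensity surface.  If no row yields an interface point (e.g.
    density increasing monotonically outward - not a droplet) an
    :class:`InterfaceError` is raised.
    """
    if rho_bulk is None:
        rho_bulk = estimate_bulk_density(field)
    thr = threshold_fraction * rho_bulk
    rc = field.r_centers
    points = []
    for i, zc in enumerate(field.z_centers):
        if z_min is not None and zc < z_min:
            continue
        row = field.density[i]
        if row.max() < min_plateau_fraction * rho_bulk:
            continue
        r_cross = _row_crossing(rc, row, thr)
        if r_cross is not None:
            points.append((r_cross, zc))
    if not points:
        raise InterfaceError(
            "no density crossing found in any z row: not a droplet profile")
    return np.array(points)


def _axis_circle(points: np.ndarray):
    """Least-squares circle with its center on the symmetry axis (r = 0).

    The interface points come from a cylindrically averaged density, so
    the fitted sphere cross-section must be centered on the droplet axis;
    constraining the center removes the radius-shrinking bias of free
    algebraic circle fits on shallow arcs.  An algebraic (linear) solve
    seeds a geometric refinement of the radial residuals.
    """
    from scipy.optimize import least_squares

    r, z = points[:, 0], points[:, 1]
    # collinearity check on the raw points
    centered = points - points.mean(axis=0)
    svals = np.linalg.svd(centered, compute_uv=False)
    if svals[0] == 0 or svals[1] / svals[0] < 1e-8:
        raise InterfaceError(
            "interface points are collinear; cannot fit a circle")
    # linear solve of r^2 + z^2 = 2 z zc + (R^2 - zc^2)
    a = np.column_stack([2 * z, np.ones_like(z)])
    (zc, c), *_ = np.linalg.lstsq(a, r * r + z * z, rcond=None)
    rad2 = c + zc * zc
    if rad2 <= 0:
        raise InterfaceError("degenerate circle fit")
    fit = least_squares(lambda p: np.hypot(r, z - p[0]) - p[1],
                        [zc, math.sqrt(rad2)])
    zc, rad = fit.x
    if rad <= 0:
        raise InterfaceError("degenerate circle fit")
    return float(zc), float(rad)


def fit_contact_angle(points: np.ndarray, z_exclude: float = 0.8,
                      z_contact: float = 0.0) -> ContactAngleResult:
    """Fit a circle to interface points and extract the contact angle.

    Points with z <= ``z_exclude`` are discarded (the density-layered
    region near the wall distorts the spherical cap).  The circle center
    is constrained to the symmetry axis; its tangent is extrapolated down
    to ``z_contact`` and the angle with the surface plane, measured
    through the liquid, is

        theta = 90 deg + arcsin((z_c - z_contact) / R)

    for a circle centered at height z_c with radius R.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    pts = points[points[:, 1] > z_exclude]
    if len(pts) < 5:
        raise InterfaceError(
            f"need >= 5 interface points above z_exclude = {z_exclude} nm, "
            f"got {len(pts)}")
    zc, rad = _axis_circle(pts)
    s = (zc - z_contact) / rad
    if abs(s) >= 1.0:
        raise InterfaceError(
            "fitted circle does not intersect the contact plane")
    theta = 90.0 + math.degrees(math.asin(s))
    resid = float(np.sqrt(np.mean(
        (np.hypot(pts[:, 0], pts[:, 1] - zc) - rad) ** 2)))
    return ContactAngleResult(theta, (0.0, zc), rad, resid, len(pts),
                              z_exclude, z_contact)


def contact_angle_from_frames(frames, dr: float = 0.1, dz: float = 0.05,
                              z_exclude: float = 0.8, z_contact: float = 0.0,
                              threshold_fraction: float = 0.5,
                              rho_bulk: float | None = None) -> ContactAngleResult:
    """Full chain: frames -> density field -> interface -> contact angle."""
    field = density_field(frames, dr=dr, dz=dz)
    pts = extract_interface(field, threshold_fraction, z_min=z_exclude,
                            rho_bulk=rho_bulk)
    return fit_contact_angle(pts, z_exclude=z_exclude, z_contact=z_contact)


def huang_relative_friction(theta_a: float, theta_b: float) -> float:
    """Relative friction (1 + cos a)^2 / (1 + cos b)^2 from two contact angles.

    Angles in degrees, each strictly inside (0, 180).
    """
    for th in (theta_a, theta_b):
        if not 0.0 < th < 180.0:
            raise ValueError(f"contact angle {th} deg outside (0, 180)")
    na = 1.0 + math.cos(math.radians(theta_a))
    nb = 1.0 + math.cos(math.radians(theta_b))
    return (na / nb) ** 2
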