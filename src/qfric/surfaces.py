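"""Builders for planar model surfaces with heterogeneous partial charges.

Three surface families are supported:

* a honeycomb (graphene-like) lattice decorated with +q/-q pairs placed on
  diagonally opposite (para) vertices of hexagons,
* a square lattice with a +q/-q checkerboard decoration,
* a plane of rigid methylene (CH2) groups with q_C = -2 q_H.

All builders guarantee exact overall charge neutrality: a decoration that
cannot tile the requested supercell raises :class:`SurfaceBuildError`
instead of silently leaving a net charge.  Surfaces are periodic in x and
y; the heavy-atom layer sits at ``z_plane`` and water occupies z > z_plane.
Lengths are in nm, charges in e.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import constants as const

__all__ = [
    "SurfaceAtom",
    "Surface",
    "LatticeSpec",
    "SurfaceBuildError",
    "StructureParseError",
    "build_hexagonal",
    "build_square",
    "build_ch2",
    "write_structure",
    "read_structure",
]


class SurfaceBuildError(ValueError):
    """Raised when a lattice/decoration combination cannot tile periodically."""


class StructureParseError(ValueError):
    """Raised when a structure file or its parameter sidecar cannot be parsed."""


@dataclass(frozen=True)
class SurfaceAtom:
    """One rigid surface atom.

    Parameters
    ----------
    label:
        Short element-like label ("C", "H", "S", ...).
    position:
        Cartesian position in nm.
    charge:
        Partial charge in e; must satisfy ``|charge| <= 1``.
    lj_epsilon, lj_sigma:
        Lennard-Jones well depth (kJ/mol) and size (nm).
    """

    label: str
    position: tuple
    charge: float = 0.0
    lj_epsilon: float = const.SOLID_LJ_EPSILON
    lj_sigma: float = const.SOLID_LJ_SIGMA

    def __post_init__(self):
        object.__setattr__(
            self, "position", tuple(float(x) for x in self.position)
        )
        if len(self.position) != 3:
            raise ValueError("position must be a 3-vector")
        if self.lj_epsilon < 0:
            raise ValueError("lj_epsilon must be >= 0")
        if self.lj_sigma <= 0:
            raise ValueError("lj_sigma must be > 0")
        if abs(self.charge) > 1.0:
            raise ValueError(f"|charge| = {abs(self.charge)} e exceeds 1.0 e")


@dataclass
class Surface:
    """A periodic planar surface: atoms plus two in-plane lattice vectors."""

    atoms: list
    cell: np.ndarray  # (2, 2) rows = in-plane periodic vectors, nm
    z_plane: float = 0.0
    kind: str = "custom"
    meta: dict = field(default_factory=dict)
    _cache: dict = field(default_factory=dict, init=False, repr=False, compare=False)

    def __post_init__(self):
        self.cell = np.asarray(self.cell, dtype=float).reshape(2, 2)
        if not self.atoms:
            raise ValueError("surface must contain at least one atom")

    # -- array views -------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def positions(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    @property
    def charges(self) -> np.ndarray:
        return np.array([a.charge for a in self.atoms], dtype=float)

    @property
    def lj_epsilons(self) -> np.ndarray:
        return np.array([a.lj_epsilon for a in self.atoms], dtype=float)

    @property
    def lj_sigmas(self) -> np.ndarray:
        return np.array([a.lj_sigma for a in self.atoms], dtype=float)

    @property
    def labels(self) -> list:
        return [a.label for a in self.atoms]

    # -- geometry ----------------------------------------------------
    @property
    def rect_lengths(self) -> tuple:
        """(Lx, Ly) for a rectangular cell; raises if the cell is oblique."""
        c = self.cell
        if abs(c[0, 1]) > 1e-12 or abs(c[1, 0]) > 1e-12:
            raise ValueError("operation requires a rectangular periodic cell")
        return float(c[0, 0]), float(c[1, 1])

    @property
    def area(self) -> float:
        """In-plane cell area, nm^2."""
        return float(abs(np.linalg.det(self.cell)))

    @property
    def total_charge(self) -> float:
        # fsum returns the correctly rounded true sum, hence exactly 0.0
        # for balanced +q/-q decorations.
        return math.fsum(a.charge for a in self.atoms)

    def translated(self, shift) -> "Surface":
        """Return a copy rigidly translated in-plane and re-wrapped into the cell."""
        lx, ly = self.rect_lengths
        sx, sy = float(shift[0]), float(shift[1])
        atoms = []
        for a in self.atoms:
            x = (a.position[0] + sx) % lx
            y = (a.position[1] + sy) % ly
            atoms.append(
                SurfaceAtom(a.label, (x, y, a.position[2]), a.charge,
                            a.lj_epsilon, a.lj_sigma)
            )
        return Surface(atoms, self.cell.copy(), self.z_plane, self.kind,
                       dict(self.meta))


@dataclass
class LatticeSpec:
    """Parameters of a periodic lattice surface.

    ``bond_length`` applies to the honeycomb lattice (nearest-neighbour
    C-C distance); ``lattice_constant`` to the square lattice and to the
    CH2 group packing.  ``q`` is the charge-decoration magnitude in e and
    ``decoration`` selects the charge pattern (builder-specific id).
    """

    kind: str
    nx: int = 1
    ny: int = 1
    q: float = 0.0
    bond_length: float = 0.142
    lattice_constant: float = 0.25
    decoration: str | None = None

    def __post_init__(self):
        if self.nx < 1 or self.ny < 1:
            raise ValueError("nx and ny must be >= 1")
        if self.q < 0:
            raise ValueError("charge magnitude q must be >= 0")
        if self.bond_length <= 0 or self.lattice_constant <= 0:
            raise ValueError("lattice lengths must be > 0")


def build_hexagonal(spec: LatticeSpec) -> Surface:
    """Build a honeycomb sheet with +q/-q pairs on para hexagon vertices.

    The orthorhombic repeat unit contains four atoms and measures
    sqrt(3)*b x 3*b (b = bond length); ``nx = 26, ny = 16`` with
    b = 0.142 nm reproduces a 6.395 x 6.816 nm footprint.  Decorations:

    * ``"para"`` (default): every repeat unit carries one +q and one -q
      atom, 2 bonds == one hexagon diagonal apart (para positions).
    * ``"para-sparse"``: every other repeat unit (checkerboard of units)
      is decorated; requires even nx and ny.
    * ``"none"``: all atoms neutral.
    """
    if spec.kind != "hexagonal":
        raise SurfaceBuildError(f"expected kind 'hexagonal', got {spec.kind!r}")
    b = spec.bond_length
    ax, ay = math.sqrt(3.0) * b, 3.0 * b
    # honeycomb basis of the 4-atom rectangular unit
    basis = [
        (0.0, 0.0),
        (ax / 2.0, b / 2.0),
        (ax / 2.0, 3.0 * b / 2.0),
        (0.0, 2.0 * b),
    ]
    deco = spec.decoration or "para"
    if deco == "para":
        def decorated(i, j):
            return True
    elif deco == "para-sparse":
        if spec.nx % 2 or spec.ny % 2:
            raise SurfaceBuildError(
                "decoration 'para-sparse' tiles only for even nx and ny; "
                f"got nx={spec.nx}, ny={spec.ny}"
            )
        def decorated(i, j):
            return (i + j) % 2 == 0
    elif deco == "none":
        def decorated(i, j):
            return False
    else:
        raise SurfaceBuildError(f"unknown hexagonal decoration {deco!r}")

    atoms = []
    for i in range(spec.nx):
        for j in range(spec.ny):
            on = decorated(i, j)
            for k, (bx, by) in enumerate(basis):
                charge = 0.0
                if on and k == 0:
                    charge = +spec.q
                elif on and k == 3:
                    charge = -spec.q
                atoms.append(
                    SurfaceAtom("C", (i * ax + bx, j * ay + by, 0.0), charge)
                )
    cell = np.diag([spec.nx * ax, spec.ny * ay])
    return Surface(atoms, cell, 0.0, "hexagonal",
                   {"decoration": deco, "q": spec.q, "bond_length": b,
                    "nx": spec.nx, "ny": spec.ny})


def build_square(spec: LatticeSpec) -> Surface:
    """Build a square lattice with an alternating +q/-q checkerboard.

    The checkerboard pattern tiles the periodic supercell only for even
    repeat counts; odd nx/ny with q > 0 raise :class:`SurfaceBuildError`.
    """
    if spec.kind != "square":
        raise SurfaceBuildError(f"expected kind 'square', got {spec.kind!r}")
    a = spec.lattice_constant
    deco = spec.decoration or "checkerboard"
    if deco not in ("checkerboard", "none"):
        raise SurfaceBuildError(f"unknown square decoration {deco!r}")
    if deco == "checkerboard" and spec.q > 0 and (spec.nx % 2 or spec.ny % 2):
        raise SurfaceBuildError(
            "checkerboard decoration tiles only for even nx and ny; "
            f"got nx={spec.nx}, ny={spec.ny}"
        )
    atoms = []
    for i in range(spec.nx):
        for j in range(spec.ny):
            if deco == "none" or spec.q == 0:
                charge = 0.0
            else:
                charge = +spec.q if (i + j) % 2 == 0 else -spec.q
            atoms.append(SurfaceAtom("S", (i * a, j * a, 0.0), charge))
    cell = np.diag([spec.nx * a, spec.ny * a])
    return Surface(atoms, cell, 0.0, "square",
                   {"decoration": deco, "q": spec.q, "lattice_constant": a,
                    "nx": spec.nx, "ny": spec.ny})


def build_ch2(spec: LatticeSpec, q_h: float = 0.06) -> Surface:
    """Build a plane of rigid CH2 groups with q_C = -2 q_H.

    Each group has the carbon in the z = 0 plane and two hydrogens tilted
    symmetrically toward the water side (C-H 0.109 nm, H-C-H 109.5 deg).
    ``q_h`` is the hydrogen charge in e and must lie in [0, 0.36]; the
    group is neutral by construction.
    """
    if spec.kind != "ch2":
        raise SurfaceBuildError(f"expected kind 'ch2', got {spec.kind!r}")
    if not 0.0 <= q_h <= 0.36:
        raise ValueError(f"q_h = {q_h} e outside the supported range [0, 0.36]")
    a = spec.lattice_constant
    d_ch = 0.109
    half = math.radians(109.5 / 2.0)
    dx, dz = d_ch * math.sin(half), d_ch * math.cos(half)
    atoms = []
    for i in range(spec.nx):
        for j in range(spec.ny):
            x, y = i * a, j * a
            atoms.append(SurfaceAtom(
                "C", (x, y, 0.0), -2.0 * q_h,
                const.CH2_C_LJ_EPSILON, const.CH2_C_LJ_SIGMA))
            for s in (-1.0, +1.0):
                atoms.append(SurfaceAtom(
                    "H", (x + s * dx, y, dz), q_h,
                    const.CH2_H_LJ_EPSILON, const.CH2_H_LJ_SIGMA))
    cell = np.diag([spec.nx * a, spec.ny * a])
    return Surface(atoms, cell, 0.0, "ch2",
                   {"q_h": q_h, "lattice_constant": a,
                    "nx": spec.nx, "ny": spec.ny})


# ---------------------------------------------------------------------
# Structure file I/O.  XYZ/GRO carry positions only; charges, LJ
# parameters, the periodic cell and the surface kind travel in a CSV
# sidecar, which is part of the on-disk contract.
# ---------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".csv")


def write_structure(surface: Surface, path, fmt: str | None = None,
                    params_path=None) -> Path:
    """Write a surface to ``path`` (.xyz in A, .gro in nm) plus a CSV sidecar.

    Returns the sidecar path.  The sidecar columns are
    ``index,label,charge_e,epsilon_kJmol,sigma_nm`` and its commented
    header stores the cell vectors, z_plane and kind.
    """
    import MDAnalysis as mda

    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt not in ("xyz", "gro"):
        raise ValueError(f"unknown structure format {fmt!r}")
    n = surface.n_atoms
    u = mda.Universe.empty(n, n_residues=1,
                           atom_resindex=np.zeros(n, dtype=int),
                           trajectory=True)
    u.add_TopologyAttr("names", surface.labels)
    u.add_TopologyAttr("resnames", ["SUR"])
    u.add_TopologyAttr("resids", [1])
    u.atoms.positions = surface.positions * 10.0  # nm -> A
    lx, ly = surface.rect_lengths
    u.dimensions = [lx * 10.0, ly * 10.0, 210.0, 90.0, 90.0, 90.0]
    u.atoms.write(str(path))

    params_path = Path(params_path) if params_path else _sidecar_path(path)
    with open(params_path, "w") as fh:
        fh.write("# qfric surface sidecar v1\n")
        fh.write(f"# kind={surface.kind}\n")
        fh.write(f"# z_plane={surface.z_plane!r}\n")
        fh.write("# cell=" + ",".join(repr(float(v))
                                      for v in surface.cell.ravel()) + "\n")
        pd.DataFrame({
            "index": np.arange(n),
            "label": surface.labels,
            "charge_e": surface.charges,
            "epsilon_kJmol": surface.lj_epsilons,
            "sigma_nm": surface.lj_sigmas,
        }).to_csv(fh, index=False)
    return params_path


def _parse_sidecar(params_path: Path):
    meta = {}
    try:
        with open(params_path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.startswith("#"):
                    break
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, _, val = body.partition("=")
                    meta[key.strip()] = val.strip()
        df = pd.read_csv(params_path, comment="#")
    except FileNotFoundError:
        raise StructureParseError(f"missing parameter sidecar {params_path}")
    except Exception as exc:  # malformed CSV
        raise StructureParseError(
            f"could not parse sidecar {params_path}: {exc}") from exc
    required = {"index", "label", "charge_e", "epsilon_kJmol", "sigma_nm"}
    missing = required - set(df.columns)
    if missing:
        raise StructureParseError(
            f"sidecar {params_path} lacks columns {sorted(missing)} "
            f"(line {len(meta) + 1})")
    return meta, df


def read_structure(path, params_path=None) -> Surface:
    """Read a surface written by :func:`write_structure`.

    Positions are reproduced to format precision (GRO: 0.001 nm) and
    charges/LJ parameters are restored from the sidecar.
    """
    import MDAnalysis as mda

    path = Path(path)
    if path.exists() and path.stat().st_size == 0:
        raise StructureParseError(f"{path}: empty file (line 1)")
    try:
        u = mda.Universe(str(path))
        pos = u.atoms.positions / 10.0  # A -> nm
    except StructureParseError:
        raise
    except Exception as exc:
        raise StructureParseError(f"could not parse {path}: {exc}") from exc

    params_path = Path(params_path) if params_path else _sidecar_path(path)
    meta, df = _parse_sidecar(params_path)
    if len(df) != len(pos):
        raise StructureParseError(
            f"sidecar {params_path} has {len(df)} rows but {path} has "
            f"{len(pos)} atoms")
    if "cell" in meta:
        cell = np.array([float(v) for v in meta["cell"].split(",")]).reshape(2, 2)
    else:
        dim = u.dimensions
        cell = np.diag([dim[0] / 10.0, dim[1] / 10.0])
    z_plane = float(meta.get("z_plane", 0.0))
    kind = meta.get("kind", "custom")
    df = df.sort_values("index")
    atoms = [
        SurfaceAtom(str(lab), tuple(pos[int(i)]), float(q), float(eps), float(sig))
        for i, lab, q, eps, sig in zip(
            df["index"], df["label"], df["charge_e"],
            df["epsilon_kJmol"], df["sigma_nm"])
    ]
    return Surface(atoms, cell, z_plane, kind)
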