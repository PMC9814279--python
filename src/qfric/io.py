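"""Trajectory I/O helpers shared by the analysis modules.

Water trajectories are multi-frame XYZ/GRO files with atoms in repeating
(O, H, H) triples; droplet point clouds - whose molecule count varies
frame to frame - use a long-format CSV with columns frame,x,y,z (nm).
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .energymap import WaterConfig
from .surfaces import StructureParseError


def write_water_frames(path, frames, cell_lengths=(10.0, 10.0, 21.0)) -> None:
    """Write frames of :class:`WaterConfig` lists as a multi-frame XYZ/GRO.

    All frames must hold the same number of molecules.
    """
    import MDAnalysis as mda

    frames = list(frames)
    if not frames:
        raise ValueError("no frames to write")
    n_mol = len(frames[0])
    if any(len(f) != n_mol for f in frames):
        raise ValueError("all frames must hold the same number of molecules")
    if str(path).endswith(".gro") and len(frames) > 1:
        raise ValueError(
            "GRO holds a single configuration; use XYZ for trajectories")
    n_atoms = 3 * n_mol
    u = mda.Universe.empty(n_atoms, n_residues=n_mol,
                           atom_resindex=np.repeat(np.arange(n_mol), 3),
                           trajectory=True)
    u.add_TopologyAttr("names", ["OW", "HW1", "HW2"] * n_mol)
    u.add_TopologyAttr("resnames", ["SOL"] * n_mol)
    u.add_TopologyAttr("resids", np.arange(1, n_mol + 1))
    u.dimensions = [cell_lengths[0] * 10, cell_lengths[1] * 10,
                    cell_lengths[2] * 10, 90, 90, 90]
    if str(path).endswith(".gro"):
        u.atoms.positions = np.concatenate(
            [wc.sites() for wc in frames[0]]) * 10.0
        u.atoms.write(str(path))
        return
    with mda.Writer(str(path), n_atoms=n_atoms, multiframe=True) as w:
        for frame in frames:
            u.atoms.positions = np.concatenate(
                [wc.sites() for wc in frame]) * 10.0
            w.write(u.atoms)


def read_water_frames(path) -> list:
    """Read a water trajectory back into frames of :class:`WaterConfig`.

    Atoms are grouped into consecutive (O, H, H) triples.
    """
    import MDAnalysis as mda

    path = Path(path)
    if path.exists() and path.stat().st_size == 0:
        raise StructureParseError(f"{path}: empty file (line 1)")
    try:
        u = mda.Universe(str(path))
    except Exception as exc:
        raise StructureParseError(f"could not parse {path}: {exc}") from exc
    if len(u.atoms) % 3:
        raise StructureParseError(
            f"{path}: atom count {len(u.atoms)} is not a multiple of 3")
    frames = []
    for _ in u.trajectory:
        pos = u.atoms.positions / 10.0
        frames.append([
            WaterConfig(tuple(pos[i]), tuple(pos[i + 1]), tuple(pos[i + 2]))
            for i in range(0, len(pos), 3)])
    return frames


def write_droplet_csv(path, frames) -> None:
    """Write droplet point frames (list of (N, 3) arrays, nm) to CSV."""
    rows = []
    for k, pts in enumerate(frames):
        pts = np.asarray(pts, dtype=float).reshape(-1, 3)
        rows.append(pd.DataFrame(
            {"frame": k, "x": pts[:, 0], "y": pts[:, 1], "z": pts[:, 2]}))
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def read_droplet_csv(path) -> list:
    """Read droplet point frames written by :func:`write_droplet_csv`."""
    df = pd.read_csv(path, comment="#")
    for col in ("frame", "x", "y", "z"):
        if col not in df.columns:
            raise StructureParseError(f"{path}: missing column {col!r}")
    return [g[["x", "y", "z"]].to_numpy()
            for _, g in df.groupby("frame", sort=True)]
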