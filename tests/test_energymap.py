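"""Energy maps: pair energies, layer selection, grids and map statistics."""
import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from qfric import (
    EnergyGrid,
    GridError,
    LatticeSpec,
    SPCE,
    Surface,
    SurfaceAtom,
    WaterConfig,
    accumulate_map,
    build_square,
    interface_energy_density,
    map_stats,
    pair_energy,
    probe_map,
    select_first_layer,
)
from qfric import constants as const


def water_at(x, y, z, rotation=None):
    return WaterConfig.from_pose([x, y, z], rotation)


def isolated_atom_surface(charge=0.0, big=8.0):
    atom = SurfaceAtom("C", (big / 2, big / 2, 0.0), charge)
    return Surface([atom], np.diag([big, big]), 0.0, "custom")


# ------------------------------------------------------------------
# pair_energy
# ------------------------------------------------------------------

def test_neutral_surface_has_zero_coulomb():
    surf = build_square(LatticeSpec("square", 4, 4, q=0.0))
    pe = pair_energy(water_at(0.37, 0.12, 0.31), surf)
    assert pe.coulomb == 0.0
    assert pe.lj != 0.0


def test_lj_zero_crossing_at_sigma():
    # O directly above one isolated neutral atom at r = sigma_OS: the LJ
    # pair term vanishes (water H carry no LJ, charges are zero)
    surf = isolated_atom_surface()
    sigma_os = 0.5 * (SPCE.o_sigma + const.SOLID_LJ_SIGMA)
    w = water_at(4.0, 4.0, sigma_os)
    pe = pair_energy(w, surf)
    assert pe.coulomb == 0.0
    assert pe.lj == pytest.approx(0.0, abs=1e-12)


def test_pair_energy_matches_hand_sum():
    # 2-atom surface in a huge cell (no images within cutoff), arbitrary
    # water pose: compare against an explicit pairwise loop
    big = 8.0
    atoms = [SurfaceAtom("C", (3.9, 4.0, 0.0), 0.2),
             SurfaceAtom("C", (4.1, 4.0, 0.0), -0.2)]
    surf = Surface(atoms, np.diag([big, big]))
    rot = Rotation.from_euler("xyz", [0.3, 1.1, -0.4])
    w = water_at(4.02, 3.95, 0.33, rot)

    lj_ref = coul_ref = 0.0
    for a in atoms:
        r_o = np.linalg.norm(w.sites()[0] - np.array(a.position))
        if r_o > 1.0:  # group cutoff on the O-atom distance
            continue
        for site, q_site in zip(w.sites(), SPCE.site_charges):
            r = np.linalg.norm(site - np.array(a.position))
            coul_ref += const.KE * q_site * a.charge / r
        eps = math.sqrt(SPCE.o_epsilon * a.lj_epsilon)
        sig = 0.5 * (SPCE.o_sigma + a.lj_sigma)
        lj_ref += 4 * eps * ((sig / r_o) ** 12 - (sig / r_o) ** 6)

    pe = pair_energy(w, surf)
    assert pe.lj == pytest.approx(lj_ref, rel=1e-12)
    assert pe.coulomb == pytest.approx(coul_ref, rel=1e-12)
    assert pe.total == pytest.approx(lj_ref + coul_ref, rel=1e-12)


def test_overlap_flagged_but_energy_returned():
    surf = isolated_atom_surface()
    pe = pair_energy(water_at(4.0, 4.0, 0.01), surf)
    assert pe.overlap
    assert np.isfinite(pe.total)


def test_coulomb_continuous_lj_fixed_when_cutoff_grows(square_surface):
    w = water_at(0.13, 0.41, 0.30)
    e1 = pair_energy(w, square_surface, cutoff=1.0)
    e2 = pair_energy(w, square_surface, cutoff=1.001)
    # enlarging the cutoff changes Coulomb only slightly (continuity)
    assert abs(e2.coulomb - e1.coulomb) < 0.5
    assert e2.coulomb != e1.coulomb or e2.lj == e1.lj


# ------------------------------------------------------------------
# first layer selection
# ------------------------------------------------------------------

def test_first_layer_boundaries(square_surface):
    frame = [water_at(0.1, 0.1, 1.0), water_at(0.2, 0.2, 0.50),
             water_at(0.3, 0.3, 0.0), water_at(0.4, 0.4, 0.25)]
    layer = select_first_layer(frame, square_surface)
    zs = sorted(w.o[2] for w in layer)
    # z = 0.50 included (closed top), z = 0 and z = 1.0 excluded
    assert zs == [0.25, 0.50]


def test_first_layer_empty_allowed(square_surface):
    assert select_first_layer(
        [water_at(0.1, 0.1, 1.0)], square_surface) == []


def test_first_layer_matches_brute_force_filter(square_surface, rng):
    frame = [water_at(*rng.random(2), z) for z in rng.uniform(0, 1.2, 50)]
    layer = select_first_layer(frame, square_surface)
    ref = [w for w in frame if 0 < w.o[2] <= 0.5]
    assert layer == ref


# ------------------------------------------------------------------
# accumulate_map
# ------------------------------------------------------------------

def test_single_water_single_frame_single_cell(square_surface):
    w = water_at(0.13, 0.41, 0.30)
    grid = accumulate_map([[w]], square_surface, edge=0.05)
    assert grid.counts.sum() == 1
    ix, iy = np.argwhere(grid.counts == 1)[0]
    assert (ix, iy) == (int(0.13 / 0.05), int(0.41 / 0.05))
    pe = pair_energy(w, square_surface)
    assert grid.values[ix, iy] == pytest.approx(pe.total, rel=1e-12)


def test_counts_equal_total_layer_observations(square_surface, rng):
    frames = [[water_at(*(rng.random(2)), rng.uniform(0, 1.0))
               for _ in range(20)] for _ in range(5)]
    grid = accumulate_map(frames, square_surface, edge=0.05)
    n_layer = sum(len(select_first_layer(f, square_surface)) for f in frames)
    assert grid.counts.sum() == n_layer
    assert np.all(np.isnan(grid.mean_total[grid.mask]))


def test_q0_map_is_pure_lj(rng):
    surf = build_square(LatticeSpec("square", 4, 4, q=0.0))
    frames = [[water_at(*(rng.random(2)), 0.3) for _ in range(30)]]
    grid = accumulate_map(frames, surf, edge=0.05)
    assert np.all(grid.mean_coulomb[~grid.mask] == 0.0)


def test_cell_mean_is_quadrature_average(square_surface):
    # uniform sampling over one cell approaches the quadrature average of
    # pair_energy over that cell (fixed z and orientation)
    n = 6
    xs = (np.arange(n) + 0.5) / n * 0.05
    waters = [water_at(x, y, 0.31) for x in xs for y in xs]
    grid = accumulate_map([waters], square_surface, edge=0.05)
    ref = np.mean([pair_energy(w, square_surface).total for w in waters])
    assert grid.values[0, 0] == pytest.approx(ref, rel=1e-12)
    assert grid.counts[0, 0] == n * n


def test_incommensurate_edge_raises_with_suggestion(square_surface):
    with pytest.raises(GridError, match="commensurate"):
        accumulate_map([[water_at(0.1, 0.1, 0.3)]], square_surface, edge=0.07)


def test_per_molecule_averaging(square_surface):
    w1 = water_at(0.12, 0.12, 0.30)
    w2 = water_at(0.13, 0.13, 0.35)
    grid = accumulate_map([[w1], [w2]], square_surface, per_molecule=True)
    assert grid.counts.sum() == 1
    e1 = pair_energy(w1, square_surface).total
    e2 = pair_energy(w2, square_surface).total
    ix, iy = np.argwhere(grid.counts == 1)[0]
    assert grid.values[ix, iy] == pytest.approx((e1 + e2) / 2, rel=1e-12)


# ------------------------------------------------------------------
# probe_map
# ------------------------------------------------------------------

def test_single_orientation_probe_is_plain_field(square_surface):
    rot = Rotation.identity()
    grid = probe_map(square_surface, 0.33, orientations=rot, edge=0.25)
    for i, x in enumerate(grid.x_centers):
        for j, y in enumerate(grid.y_centers):
            pe = pair_energy(water_at(x, y, 0.33, rot), square_surface)
            assert grid.values[i, j] == pytest.approx(pe.total, rel=1e-9)


def test_coulomb_component_doubles_with_charge():
    s1 = build_square(LatticeSpec("square", 4, 4, q=0.15))
    s2 = build_square(LatticeSpec("square", 4, 4, q=0.30))
    g1 = probe_map(s1, 0.33, orientations=4, weighting="uniform", edge=0.1)
    g2 = probe_map(s2, 0.33, orientations=4, weighting="uniform", edge=0.1)
    assert np.allclose(g2.mean_coulomb, 2.0 * g1.mean_coulomb, rtol=1e-12)
    assert np.allclose(g2.mean_lj, g1.mean_lj, rtol=1e-12)


def test_probe_map_periodic_under_lattice_translation(square_surface):
    a = 0.25  # lattice constant; 5 grid cells of 0.05 nm
    g0 = probe_map(square_surface, 0.33, orientations=2, edge=0.05)
    moved = square_surface.translated((a, 0.0))
    g1 = probe_map(moved, 0.33, orientations=2, edge=0.05)
    assert np.allclose(g1.mean_total, np.roll(g0.mean_total, 5, axis=0),
                       rtol=1e-9, atol=1e-9)


def test_empty_orientation_set_rejected(square_surface):
    with pytest.raises(ValueError, match="orientation"):
        probe_map(square_surface, 0.33, orientations=0)


def test_boltzmann_weighting_prefers_low_energy(square_surface):
    gu = probe_map(square_surface, 0.31, orientations=16,
                   weighting="uniform", edge=0.25)
    gb = probe_map(square_surface, 0.31, orientations=16,
                   weighting="boltzmann", edge=0.25)
    assert np.all(gb.mean_total <= gu.mean_total + 1e-12)


# ------------------------------------------------------------------
# map_stats
# ------------------------------------------------------------------

def _grid_from(values, counts=None):
    values = np.asarray(values, dtype=float)
    counts = (np.ones_like(values, dtype=int) if counts is None
              else np.asarray(counts))
    return EnergyGrid((0.05, 0.05), (1.0, 1.0), values,
                      values, np.zeros_like(values), counts)


def test_constant_map_has_zero_variance():
    stats = map_stats(_grid_from([[1.7, 1.7], [1.7, 1.7]]))
    assert stats.var_e == 0.0


def test_four_cell_hand_variance():
    vals = [[1.0, 2.0], [3.0, 6.0]]
    stats = map_stats(_grid_from(vals))
    assert stats.mean_e == pytest.approx(3.0)
    assert stats.var_e == pytest.approx(np.var([1, 2, 3, 6]))
    assert stats.n_cells == 4


def test_occupancy_weighting():
    stats = map_stats(_grid_from([[1.0, 3.0]], [[3, 1]]),
                      weighting="occupancy")
    assert stats.mean_e == pytest.approx(1.5)


def test_too_few_cells_rejected():
    grid = _grid_from([[1.0, 2.0]], [[1, 0]])
    with pytest.raises(ValueError, match="2 unmasked"):
        map_stats(grid)


def test_histogram_broadens_with_charge():
    # on fixed probe geometry the E_micro distribution widens as q grows
    stds = []
    for q in (0.0, 0.1, 0.2, 0.3):
        surf = build_square(LatticeSpec("square", 4, 4, q=q))
        grid = probe_map(surf, 0.33, orientations=8, weighting="uniform",
                         edge=0.05)
        stds.append(map_stats(grid).std_e)
    assert all(b >= a for a, b in zip(stds, stds[1:]))


# ------------------------------------------------------------------
# interface energy density
# ------------------------------------------------------------------

def test_single_water_density_is_energy_over_area(square_surface):
    w = water_at(0.3, 0.3, 0.4)
    e = pair_energy(w, square_surface).total
    dens = interface_energy_density([[w]], square_surface)
    assert dens == pytest.approx(e / square_surface.area, rel=1e-12)


def test_density_is_intensive():
    small = build_square(LatticeSpec("square", 4, 4, q=0.1))
    large = build_square(LatticeSpec("square", 8, 4, q=0.1))
    waters = [water_at(0.1 + 0.2 * i, 0.32, 0.35) for i in range(5)]
    # replicate the water pattern into the doubled cell
    doubled = waters + [water_at(w.o[0] + 1.0, w.o[1], w.o[2])
                        for w in waters]
    d_small = interface_energy_density([waters], small)
    d_large = interface_energy_density([doubled], large)
    assert d_large == pytest.approx(d_small, rel=1e-9)


def test_density_matches_brute_force_sum(square_surface, rng):
    frames = [[water_at(*(rng.random(2)), rng.uniform(0.25, 1.5))
               for _ in range(8)] for _ in range(3)]
    ref = np.mean([
        sum(pair_energy(w, square_surface).total for w in f) for f in frames
    ]) / square_surface.area
    assert interface_energy_density(frames, square_surface) == pytest.approx(
        ref, rel=1e-12)


def test_water_geometry_validation():
    w = WaterConfig.from_pose([0, 0, 0.3])
    w.validate()
    bad = WaterConfig((0, 0, 0.3), (0.2, 0, 0.3), (0, 0.2, 0.3))
    with pytest.raises(ValueError):
        bad.validate()
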