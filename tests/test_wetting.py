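"""Droplet density fields, interface extraction and contact-angle fitting."""
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qfric import (
    DensityField,
    InterfaceError,
    contact_angle_from_frames,
    density_field,
    extract_interface,
    fit_contact_angle,
    huang_relative_friction,
)
from qfric.synthetic import CapSpec, gen_droplet


def cap_points(theta_deg, radius=2.5, z_contact=0.0, n=60):
    """Exact (r, z) interface points of a spherical cap."""
    z0 = -radius * math.cos(math.radians(theta_deg)) + z_contact
    z = np.linspace(z_contact + 0.05, z0 + radius - 0.02, n)
    r = np.sqrt(radius**2 - (z - z0) ** 2)
    return np.column_stack([r, z])


def step_field(R=2.0, rho=33.0, dr=0.1, dz=0.05, height=3.0):
    r_edges = np.arange(0.0, R + 1.0 + dr, dr)
    z_edges = np.arange(0.0, height + dz, dz)
    rc = 0.5 * (r_edges[:-1] + r_edges[1:])
    dens = np.where(rc[None, :] < R, rho, 0.0) * np.ones(
        (len(z_edges) - 1, 1))
    return DensityField(r_edges, z_edges, dens, (0.0, 0.0))


# ------------------------------------------------------------------
# density_field
# ------------------------------------------------------------------

def test_uniform_slab_density_flat_in_r(rng):
    # points uniform in a cylinder: density constant across r at fixed z
    n = 400_000
    r = 3.0 * np.sqrt(rng.random(n))
    phi = rng.random(n) * 2 * math.pi
    pts = np.column_stack([r * np.cos(phi), r * np.sin(phi),
                           rng.random(n)])
    field = density_field([pts], dr=0.25, dz=0.5)
    mid = field.density[0, :10]
    expected = n / (math.pi * 9.0 * 1.0)
    assert np.all(np.abs(mid - expected) / expected < 0.1)


def test_single_molecule_single_bin():
    field = density_field([np.array([[0.0, 0.0, 0.5]])])
    assert np.count_nonzero(field.density) == 1


def test_empty_trajectory_rejected():
    with pytest.raises(ValueError, match="empty"):
        density_field([])


def test_cap_interior_density_matches_generator():
    spec = CapSpec(theta_true=90.0, n_frames=60, seed=5)
    field = density_field(gen_droplet(spec))
    rc, zc = field.r_centers, field.z_centers
    # deep interior bins of the hemisphere (R = 2.5)
    sel = (rc[None, :] < 1.2) & (zc[:, None] > 0.4) & (zc[:, None] < 1.2)
    vals = field.density[sel]
    mean = vals.mean()
    stderr = vals.std() / math.sqrt(len(vals))
    assert abs(mean - spec.rho_bulk) < 3 * stderr + 0.02 * spec.rho_bulk


# ------------------------------------------------------------------
# extract_interface
# ------------------------------------------------------------------

def test_step_profile_interface_at_exact_radius():
    field = step_field(R=2.0, rho=33.0)
    pts = extract_interface(field, rho_bulk=33.0)
    # linear interpolation between the last full and first empty bin
    # crosses rho/2 exactly at the step radius
    assert np.allclose(pts[:, 0], 2.0, atol=1e-12)


def test_tanh_profile_midpoint_within_half_bin():
    rho, R, w, dr, dz = 33.0, 2.0, 0.3, 0.1, 0.05
    r_edges = np.arange(0.0, 4.0 + dr, dr)
    z_edges = np.arange(0.0, 1.0 + dz, dz)
    rc = 0.5 * (r_edges[:-1] + r_edges[1:])
    dens = 0.5 * rho * (1 - np.tanh((rc[None, :] - R) / w)) * np.ones(
        (len(z_edges) - 1, 1))
    field = DensityField(r_edges, z_edges, dens, (0.0, 0.0))
    pts = extract_interface(field, rho_bulk=rho)
    assert np.all(np.abs(pts[:, 0] - R) < dr / 2)


def test_monotonically_increasing_density_is_not_a_droplet():
    r_edges = np.arange(0.0, 2.1, 0.1)
    z_edges = np.arange(0.0, 1.05, 0.05)
    rc = 0.5 * (r_edges[:-1] + r_edges[1:])
    dens = np.tile(rc * 20.0, (len(z_edges) - 1, 1))
    field = DensityField(r_edges, z_edges, dens, (0.0, 0.0))
    with pytest.raises(InterfaceError):
        extract_interface(field, rho_bulk=33.0)


# ------------------------------------------------------------------
# fit_contact_angle
# ------------------------------------------------------------------

def test_hemisphere_gives_ninety_degrees():
    pts = cap_points(90.0)
    res = fit_contact_angle(pts, z_exclude=0.3)
    assert res.theta == pytest.approx(90.0, abs=1e-6)
    assert res.residual < 1e-9


@pytest.mark.parametrize("theta", [60.0, 90.0, 120.0])
def test_exact_cap_points_recovered(theta):
    radius = 4.0 if theta < 75 else 2.5
    res = fit_contact_angle(cap_points(theta, radius), z_exclude=0.3)
    assert res.theta == pytest.approx(theta, abs=1e-6)
    assert res.radius == pytest.approx(radius, rel=1e-9)


def test_collinear_points_rejected():
    z = np.linspace(1.0, 2.0, 10)
    pts = np.column_stack([np.full_like(z, 1.5), z])
    with pytest.raises(InterfaceError, match="collinear"):
        fit_contact_angle(pts, z_exclude=0.3)


def test_too_few_points_rejected():
    with pytest.raises(InterfaceError, match=">= 5"):
        fit_contact_angle(cap_points(90.0)[:4], z_exclude=0.3)


def test_circle_missing_contact_plane_rejected():
    # a small circle floating high above the plane never reaches it
    z0, R = 5.0, 0.5
    phi = np.linspace(0.1, 1.2, 20)
    pts = np.column_stack([R * np.sin(phi), z0 - R * np.cos(phi)])
    with pytest.raises(InterfaceError, match="contact plane"):
        fit_contact_angle(pts, z_exclude=0.3)


# ------------------------------------------------------------------
# closed-loop recovery on synthetic caps
# ------------------------------------------------------------------

@pytest.mark.parametrize("theta", [60.0, 90.0, 120.0])
def test_noiseless_cap_recovery_within_half_degree(theta):
    frames = gen_droplet(CapSpec(theta_true=theta, n_frames=100, seed=3))
    res = contact_angle_from_frames(frames)
    assert res.theta == pytest.approx(theta, abs=0.5)


@pytest.mark.parametrize("theta", [60.0, 90.0, 120.0])
def test_noisy_cap_recovery_within_two_degrees(theta):
    frames = gen_droplet(CapSpec(theta_true=theta, n_frames=100,
                                 noise=0.03, seed=4))
    res = contact_angle_from_frames(frames)
    assert res.theta == pytest.approx(theta, abs=2.0)


def test_scale_invariance_of_fitted_angle():
    base = CapSpec(theta_true=100.0, r_sphere=2.5, n_frames=80, seed=9)
    doubled = CapSpec(theta_true=100.0, r_sphere=5.0, n_frames=40, seed=9)
    t1 = contact_angle_from_frames(gen_droplet(base)).theta
    t2 = contact_angle_from_frames(gen_droplet(doubled)).theta
    assert t1 == pytest.approx(t2, abs=0.5)


def test_angle_stable_under_exclusion_height():
    frames = gen_droplet(CapSpec(theta_true=110.0, n_frames=120, seed=7))
    thetas = [contact_angle_from_frames(frames, z_exclude=z).theta
              for z in (0.5, 0.8, 1.0)]
    assert max(thetas) - min(thetas) < 0.5


def test_recovery_over_theta_grid_with_noise():
    errs = []
    for theta in range(40, 141, 20):
        frames = gen_droplet(CapSpec(theta_true=theta, n_frames=60,
                                     noise=0.03, seed=theta))
        errs.append(abs(contact_angle_from_frames(frames).theta - theta))
    assert np.mean(errs) < 2.0


# ------------------------------------------------------------------
# relative friction from contact angles
# ------------------------------------------------------------------

def test_huang_identity_and_hemisphere():
    assert huang_relative_friction(77.0, 77.0) == 1.0
    assert huang_relative_friction(90.0, 90.0) == 1.0


def test_huang_closed_form_value():
    expected = (1 + math.cos(math.radians(68.0))) ** 2 / (
        1 + math.cos(math.radians(88.0))) ** 2
    assert huang_relative_friction(68.0, 88.0) == pytest.approx(expected)


@given(st.floats(1.0, 178.0))
@settings(max_examples=30, deadline=None, derandomize=True)
def test_huang_monotone_decreasing(theta):
    assert huang_relative_friction(theta + 1.0, 90.0) < \
        huang_relative_friction(theta, 90.0)


def test_huang_limits():
    assert huang_relative_friction(179.999, 90.0) == pytest.approx(0.0, abs=1e-6)
    assert huang_relative_friction(0.001, 90.0) == pytest.approx(4.0, abs=1e-6)


def test_huang_rejects_out_of_range():
    for bad in (0.0, 180.0, -5.0, 200.0):
        with pytest.raises(ValueError):
            huang_relative_friction(bad, 90.0)
        with pytest.raises(ValueError):
            huang_relative_friction(90.0, bad)
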