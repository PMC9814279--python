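# Methods

This note documents the models behind `qfric`, the defaults that matter,
the numerical choices, and what the synthetic generators do and do not
emulate.

## Model surfaces

All surfaces are rigid, planar and periodic in x and y, with the
heavy-atom layer at `z_plane = 0` and water at z > 0; lengths are nm,
charges e, energies kJ/mol.

**Honeycomb lattice.** Built from the 4-atom orthorhombic repeat unit of
a honeycomb sheet, √3·b × 3·b with bond length b = 0.142 nm (graphene
value; configurable).  26 × 16 repeats reproduce the 6.395 × 6.816 nm
footprint of the reference simulation box.  The default decoration
("para") places one +q and one −q atom per repeat unit on para vertices
of a hexagon (two atoms 2b apart, i.e. three bonds around the ring), so
charged sites form a periodic sublattice with equal ± counts; the
sparser variant ("para-sparse") decorates every other unit and requires
even repeat counts.  The areal density of charged pairs is a genuine
modelling freedom — it rescales (ΔE_micro)² at fixed q — which is why it
is a parameter rather than a hard-wired pattern.

**Square lattice.** One atom per site, spacing 0.25 nm by default, with a
±q checkerboard.  The checkerboard tiles a periodic supercell only for
even nx, ny; odd counts raise an error instead of silently leaving a net
charge.

**CH₂ plane.** Rigid methylene groups on square packing (0.25 nm), carbon
in-plane, two hydrogens tilted symmetrically toward the water (C–H
0.109 nm, H–C–H 109.5°).  Charges obey q_C = −2·q_H with q_H ∈
[0, 0.36] e, so each group is neutral.  The C/H Lennard-Jones parameters
default to a standard all-atom aliphatic set (C: ε 0.276 kJ/mol,
σ 0.350 nm; H: ε 0.126 kJ/mol, σ 0.250 nm) and are configurable through
the sidecar table.

Charge neutrality is exact, not approximate: builders create equal
numbers of +q and −q sites and `Surface.total_charge` uses compensated
summation, so the neutrality invariant is Σq == 0.0 in floating point.

Structure files (XYZ in Å, GRO in nm) carry positions only; partial
charges, LJ parameters, the periodic cell, z_plane and the surface kind
travel in a CSV sidecar that is part of the on-disk contract.

## Water–surface energies

Water is rigid three-site SPC/E (q_O = −0.8476 e, q_H = +0.4238 e, O–H
0.1 nm, H–O–H 109.47°, LJ on oxygen only: σ 0.3166 nm, ε 0.650 kJ/mol).
The pair energy of one water with the surface is

* LJ between the oxygen and every surface atom within the 1.0 nm cutoff,
  Lorentz–Berthelot combination by default (geometric available);
* Coulomb k_e q_i q_j / r over all water-site/surface-atom pairs.

Electrostatics are a **truncated direct sum over periodic images**, not
mesh Ewald: the cutoff is applied per charge group (all three water
sites interact with a surface atom iff the O–atom distance is within the
cutoff), so truncation never cuts through the neutral molecule and the
energy varies smoothly with the cutoff.  The exact neutrality of the
surface keeps the truncation error of the omitted far field small.  This
is a deliberate desk-scale approximation; absolute energies inherit its
accuracy.

## Energy maps and (ΔE_micro)²

E_micro is accumulated on a grid of square cells, default edge 0.05 nm
(cell area 0.25 Å²).  The grid must tile the periodic cell exactly; a
non-commensurate edge raises an error naming the nearest commensurate
edge, and `snap=True` adopts it silently.  Because a single square edge
cannot divide both lengths of the honeycomb orthorhombic cell, per-axis
edges are supported.

Two map sources exist:

* `accumulate_map` bins first-layer waters of a trajectory by their O
  (x, y) position — the first layer is the half-open slab
  (z_plane, z_plane + 0.50 nm], boundary included at the top — and
  averages the instantaneous pair energies per cell (a per-molecule
  time-average-first variant is available).  Cells without observations
  stay masked, never zero-filled.
* `probe_map` is a deterministic stand-in: a water is placed at each cell
  center at fixed height and its energy averaged over an orientation
  quadrature (32 reproducible uniform rotations by default), either
  Boltzmann-weighted at T (physical default) or uniformly.  The uniform
  average keeps the Coulomb component of the map **exactly linear in
  q** — Boltzmann weights depend on the energy and hence on q — which is
  what makes the q² checks exact: doubling q quadruples the
  Coulomb-only map variance to machine precision, and the log–log
  exponent over q ∈ {0.1, 0.2, 0.3} is 2 to ~10⁻¹⁴.

Map statistics default to unweighted means/variances over unmasked cells
(matching a standard deviation taken over the map itself); occupancy
weighting by per-cell counts is available.  The E_micro histogram uses
0.05 kJ/mol bins.  The total interface energy density sums the pair
energies of *all* waters (not only the first layer) per frame, divided
by the cell area.

## Green–Kubo friction

λ = 1/(A k_B T) ∫₀^tc dt ⟨F(t)F(0)⟩ with F the total tangential surface
force.  The ACF uses mean subtraction (an equilibrium force averages to
zero; any drift is removed) and biased 1/N normalization, which keeps
the estimator integrable; unbiased normalization is available.  The
spectral (FFT) and direct O(N·L) estimators implement the same sum and
agree to ~10⁻¹⁵; the direct path exists purely as a cross-check.

The integral is trapezoidal on the series' own time grid up to
t_cutoff = 1 ps by default — the formal upper limit is infinite, but a
liquid-like force ACF has decayed by then and the running integral,
which is always returned, should have plateaued.  A convergence flag
checks that the running integral varies by < 5% over the second half of
the window.  With F in kJ mol⁻¹ nm⁻¹, t in ps and A in nm², the
conversion to N s/m³ is the fixed constant
(10³/(N_A·10⁻⁹))² · 10⁻¹² / (A·10⁻¹⁸ · k_B T); an all-SI computation
reproduces it to rounding error.  When two force components are given,
λ is their average; the sign convention of the force is irrelevant
because λ is quadratic in F.

## Contact angles

Droplet frames are reduced to a cylindrical (r, z) number density around
the time-averaged in-plane center of mass (bins 0.1 nm in r × 0.05 nm in
z).  The bulk density is estimated in two passes: a crude volume-weighted
average locates each row's half-density radius, then bins at least
0.9 nm inside that radius are averaged (volume-weighted), keeping the
smooth interfacial tail out.  The interface is the locus where each z
row falls through 0.5·ρ_bulk, linearly interpolated between bins; rows
whose peak density never reaches 85% of ρ_bulk are discarded because
they contain no liquid interior (the cap apex region, where a horizontal
cut meets the interface at grazing incidence and the crossing no longer
tracks the isodensity surface).

A circle is fitted to the interface points above the wall-exclusion
height (z_exclude = 0.8 nm, below which density layering distorts the
cap) with its **center constrained to the symmetry axis**: the points
come from a cylindrically averaged field, so the fitted sphere
cross-section must be centered at r = 0.  A linear algebraic solve seeds
a geometric least-squares refinement.  The constraint matters: a free
three-parameter circle fit exhibits the well-known radius-shrinking bias
on shallow arcs and was several degrees off at low contact angles.
The contact angle is taken where the circle meets the contact plane
(z_contact = 0 by default): θ = 90° + arcsin((z_c − z_contact)/R),
measured through the liquid.  Recovery on synthetic caps is ≲ 0.2° at
the default sampling density and ≲ 2° with 3% positional noise over
40°–140°.

The wetting-theory route to friction, λ* ∝ (1 + cos θ)², is implemented
verbatim as the ratio (1 + cos θ_a)²/(1 + cos θ_b)².  Note that over the
88° → 68° range this ratio is ≈ 1.76; descriptions of that change as
"about 50%" understate the direct evaluation, and the package reports
the formula's value without reconciliation.

## The λ–(ΔE_micro)² model

`fit_zeta` regresses λ on (ΔE_micro)², through the origin by default
(as corrugation vanishes the Coulomb-driven friction must too; an
optional intercept absorbs the LJ floor), using only records with
ΔE_micro below 0.45 kJ/mol — beyond it the linear regime ends.  ζ's
units are fixed here as N s m⁻³ per (kJ mol⁻¹)², so numerical values
(e.g. ζ ≈ 130) are comparable only under this convention.  Records from
different lattices are fitted jointly.  `q_scaling_exponent` is a
log–log regression; q = 0 records are skipped with a warning.

## Synthetic generators

Every generator is exactly reproducible from its seed and exists so that
each analysis operation has an oracle:

* **OU forces** use the exact discrete update
  x_{k+1} = a x_k + √(σ²(1−a²)) w_k, a = e^(−dt/τ), from a stationary
  initial draw, so ⟨F(t)F(0)⟩ = σ² e^(−t/τ) holds for every finite
  sample and λ has the closed form σ²τ(1−e^(−tc/τ))/(A k_B T).  Defaults
  (A = 43.59 nm², T = 300 K) match the reference footprint.
* **Droplet caps** sample a Poisson number of points per frame at bulk
  density 33.4 nm⁻³ uniformly over a spherical cap, accepted with
  probability ½(1 − tanh((d−R)/w)) in the distance d from the sphere
  center (w = 0.3 nm, a typical simulated liquid–vapor width), so the
  half-density surface is exactly the sphere of the prescribed contact
  angle.  The "noise" parameter adds isotropic positional jitter as a
  fraction of R.  The default sphere radius grows at low angles so the
  cap stays at least 2 nm tall and the fit band above z_exclude is
  populated.
* **First-layer Monte Carlo** samples rigid single-water poses in the
  0.50 nm layer by Metropolis moves on the solid–water energy alone.
  Water–water interactions are deliberately omitted: this exercises
  layer selection, binning and the Boltzmann consistency of maps exactly
  as MD frames would, but it does not reproduce liquid structure or
  absolute friction.  At infinite temperature every in-layer move is
  accepted and the (x, y) marginal is uniform, which is tested.
* **λ–(ΔE)² datasets** are λᵢ = ζ·varEᵢ·(1 + noise·εᵢ) with Gaussian ε.

Because of these simplifications, passing tests demonstrate the
correctness and calibration of the estimators, not the MD-scale physics:
the absolute λ of a real charged surface requires the force time series
of a full simulation, which this package analyzes but does not produce.

## Problem sizes and determinism

The test-suite and acceptance defaults are desk-scale: 10⁶-sample OU
series (dt = τ/100), 100-frame droplets (~10⁵ points), 4×4 lattice
supercells with 8–32 orientation probes.  These sizes put Monte Carlo
errors comfortably inside the stated tolerances (Green–Kubo within 5% of
the closed form; contact angles within 0.5°/2°; ζ within 10% at 5%
noise).  All stochastic code takes explicit seeds; the pipeline derives
per-stage seeds from a single master seed and its JSON reports embed the
config hash and package version, so identical config + seed reproduces
byte-identical output.

## Known limitations

* Truncated electrostatics (no Ewald): absolute energies near the cutoff
  scale carry truncation error; neutrality and the charge-group cutoff
  mitigate but do not remove it.
* Rigid surfaces and rigid water only; no polarizability.
* The first layer is a fixed 0.50 nm slab, not recomputed from each
  system's density profile.
* The interface fit assumes an axisymmetric sessile droplet; it will
  reject or mis-fit films, multiple droplets, or strongly pinned shapes.
* Per-cell map averages treat observations as independent; autocorrelated
  trajectories underestimate the uncertainty of (ΔE_micro)² (no error
  bars are reported for map statistics).
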