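"""Physical constants, force-field parameters and unit conversions.

Internal unit system: energies in kJ/mol, lengths in nm, times in ps,
charges in elementary charges (e), temperatures in K.  Friction
coefficients are reported in SI units, N s/m^3.
"""

#: Boltzmann constant, kJ mol^-1 K^-1.
KB = 0.00831446261815324

#: Boltzmann constant, J K^-1 (2019 SI definition).
KB_SI = 1.380649e-23

#: Avogadro constant, mol^-1.
AVOGADRO = 6.02214076e23

#: Coulomb prefactor 1/(4 pi eps0), kJ mol^-1 nm e^-2.
KE = 138.935457644382

#: 1 kJ mol^-1 nm^-1 expressed in newton.
FORCE_TO_NEWTON = 1e3 / AVOGADRO / 1e-9

#: Conversion of a force-ACF time integral, (kJ mol^-1 nm^-1)^2 ps -> N^2 s.
ACF_INTEGRAL_TO_SI = FORCE_TO_NEWTON**2 * 1e-12

#: nm^2 -> m^2.
NM2_TO_M2 = 1e-18

# Lennard-Jones parameters of the solid atoms in the charged-lattice
# surface models (single-site, graphite-like).
SOLID_LJ_EPSILON = 0.2325  # kJ/mol
SOLID_LJ_SIGMA = 0.34      # nm

# All-atom aliphatic parameters for the rigid-CH2 plane (OPLS-AA CT/HC).
CH2_C_LJ_EPSILON = 0.276144  # kJ/mol
CH2_C_LJ_SIGMA = 0.350       # nm
CH2_H_LJ_EPSILON = 0.125520  # kJ/mol
CH2_H_LJ_SIGMA = 0.250       # nm

# SPC/E rigid three-site water (LJ on oxygen only).
SPCE_QO = -0.8476       # e
SPCE_QH = 0.4238        # e
SPCE_OH = 0.1           # nm
SPCE_ANGLE = 109.47     # degrees
SPCE_O_SIGMA = 0.3166   # nm
SPCE_O_EPSILON = 0.650  # kJ/mol
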