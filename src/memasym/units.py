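"""Physical constants and unit conversions.

Internal units throughout the package: length nm, time ps, mass amu,
charge e, energy kJ/mol, pressure bar, potential mV.
"""

#: Boltzmann constant in kJ mol^-1 K^-1.
KB_KJ_PER_MOL_K = 0.00831446261815324

#: 1 kJ mol^-1 nm^-3 expressed in bar.
KJ_PER_MOL_NM3_TO_BAR = 16.605390671738466

#: Avogadro constant, mol^-1.
AVOGADRO = 6.02214076e23

#: Elementary charge, C.
ELEMENTARY_CHARGE_C = 1.602176634e-19

#: Vacuum permittivity, F m^-1.
EPSILON0_F_PER_M = 8.8541878128e-12

#: (1 e nm^-2) / epsilon0 expressed as an electric field in V nm^-1.
#: Equivalently converts a charge per area in e/nm^2 to sigma/eps0 in V/nm.
E_PER_NM2_OVER_EPS0_V_PER_NM = (
    ELEMENTARY_CHARGE_C / (EPSILON0_F_PER_M * 1e-18) * 1e-9
)

#: 1 bar nm expressed in mN/m (for surface-tension integrals).
BAR_NM_TO_MN_PER_M = 0.1

#: Ion pairs per nm^3 at 1 mM: 1e-3 mol/L * NA / (1e24 nm^3/L).
MM_TO_PER_NM3 = 1e-3 * AVOGADRO * 1e-24
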