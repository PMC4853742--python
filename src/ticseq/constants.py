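"""Physical constants and unit conversions used throughout the package.

Internally, geometry is in angstroms and concentrations in mol/L; currents
are reported in nA.  All conversions funnel through the constants below so
that no module carries its own factors.
"""

#: Elementary charge in coulombs.
ELEMENTARY_CHARGE_C = 1.602176634e-19

#: Number density corresponding to a 1 mol/L solution, in ions per cubic
#: angstrom (Avogadro / 1e27 A^3 per m^3 * 1e-3 m^3 per L).
MOLAR_TO_PER_A3 = 6.02214076e-4

#: Same conversion expressed in ions per cubic metre.
MOLAR_TO_PER_M3 = 6.02214076e26

#: One square angstrom in square metres.
A2_TO_M2 = 1e-20

#: Amperes to nanoamperes.
A_TO_NA = 1e9

#: Default bulk electrolyte concentration (mol/L) for both K+ and Cl-.
DEFAULT_G_BULK_MOLAR = 1.0

#: Default bulk transverse flow speed in the channel (m/s).
DEFAULT_V_BULK_M_PER_S = 77.23

#: Default longitudinal channel radius (angstrom).
DEFAULT_CHANNEL_RADIUS_A = 35.0

#: Ideal inter-residue spacing along the backbone (angstrom).
RESIDUE_LENGTH_A = 3.8

#: Supported ion species labels.
ION_SPECIES = ("K+", "Cl-")


def current_nA(g_bulk_molar: float, v_bulk_m_per_s: float, area_A2: float) -> float:
    """Transverse ionic current carried by one species through a free area.

    I = q * n * v * A with n the bulk number density.  The result is in nA.
    """
    n_per_m3 = g_bulk_molar * MOLAR_TO_PER_M3
    return (
        ELEMENTARY_CHARGE_C * n_per_m3 * v_bulk_m_per_s * area_A2 * A2_TO_M2 * A_TO_NA
    )
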