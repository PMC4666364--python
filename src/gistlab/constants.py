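"""Physical constants and bulk-water reference values.

Energies are kcal/mol, lengths Å, charges elementary charges, temperatures K
throughout the package.
"""

#: Boltzmann constant, kcal/mol/K.
KB_KCAL = 0.0019872041

#: Coulomb constant k_e = 1/(4 pi eps_0) in kcal·Å/mol/e².
COULOMB_K = 332.0637

#: Bulk TIP3P water number density, Å^-3.
RHO0_BULK = 0.0329

#: Mean water-water interaction energy per bulk water (half-sum convention),
#: kcal/mol.
EPS_WW0_BULK = -9.565

#: Default analysis temperature, K.
T_DEFAULT = 298.0

#: TIP3P rigid-water geometry.
WATER_OH_LENGTH = 0.9572  # Å
WATER_HOH_ANGLE = 104.52  # degrees

#: Bondi van der Waals radii by element (Å); used as SASA defaults.
BONDI_RADII = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "P": 1.80,
    "S": 1.80,
    "F": 1.47,
    "CL": 1.75,
    "K": 2.75,
    "NA": 2.27,
    "MG": 1.73,
}
DEFAULT_RADIUS = 1.70
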