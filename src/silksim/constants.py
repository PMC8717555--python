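"""Physical constants, unit conversions and reference values used across the package."""

#: Molar gas constant, J mol^-1 K^-1.
R_GAS = 8.314

#: 1 cm^2 s^-1 expressed in A^2 ps^-1.
CM2_S_TO_A2_PS = 1.0e4

#: Standard atomic weights (g/mol) for the elements occurring in (Ala-Gly)_n + water.
ATOMIC_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
}

#: Mass of one water molecule, g/mol.
WATER_MOLAR_MASS = 18.015

# Literature reference: incorporation energy of a single water molecule in the most
# favorable inter-chain site of the (Ala-Gly)_16 silk-I crystal, from electronic-structure
# geometry optimisation.  Shipped as a documented reference constant for comparison with
# user-supplied energy triples; this package does no electronic-structure calculation.
DFT_INTERCHAIN_SITE_E_INC_KJ_MOL = -83.92
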