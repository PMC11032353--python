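"""Physical constants and unit conversions.

Internal unit system: length Å, energy kcal/mol, mass Da (g/mol), time fs,
charge in units of the elementary charge, temperature K.
"""

#: Boltzmann constant, kcal/mol/K.
KB = 0.0019872041

#: Avogadro's number, 1/mol.
NA = 6.02214076e23

#: Elementary charge, C.
EC = 1.602176634e-19

#: Vacuum permittivity, C^2 / (J m).
EPS0 = 8.8541878128e-12

#: Coulomb factor e^2/(4 pi eps0) in kcal Å / (mol e^2).
COULOMB = 332.0716

#: 1 kcal/mol expressed in Da Å^2/fs^2.  Acceleration in Å/fs^2 is
#: force[kcal/mol/Å] / mass[Da] * KCAL_TO_DA_A2_FS2.
KCAL_TO_DA_A2_FS2 = 4.184e-4

#: Joules per kcal.
J_PER_KCAL = 4184.0

#: Average residue masses, Da.
AMINO_MASSES = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
    "C": 103.1388, "E": 129.1155, "Q": 128.1307, "G": 57.0519,
    "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
    "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
    "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}

#: Integer residue charges at neutral pH (His neutral by default).
AMINO_CHARGES = {
    "D": -1.0, "E": -1.0, "K": 1.0, "R": 1.0, "H": 0.0,
}

#: Three-site DNA masses, Da: phosphate, deoxyribose sugar, and the four bases.
DNA_SITE_MASSES = {
    "P": 94.9696, "S": 83.1104,
    "A": 134.1220, "C": 110.0964, "G": 150.1214, "T": 125.1078,
}

DNA_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
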