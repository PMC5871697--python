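"""Physical constants and unit conversions.

Internal unit system is Hartree atomic units throughout; Angstrom,
kcal/mol, fs, nm and cm^-1 appear only at I/O boundaries.
"""

BOHR_PER_ANGSTROM = 1.8897261254578281
ANGSTROM_PER_BOHR = 1.0 / BOHR_PER_ANGSTROM

HARTREE_PER_KCALMOL = 1.0 / 627.5094740631
KCALMOL_PER_HARTREE = 627.5094740631

HARTREE_PER_EV = 1.0 / 27.211386245988
EV_PER_HARTREE = 27.211386245988

# time: 1 a.u. of time in femtoseconds
FS_PER_AUTIME = 0.02418884326585747
AUTIME_PER_FS = 1.0 / FS_PER_AUTIME

# hc in eV*nm  (photon energy E[eV] = EVNM / lambda[nm])
EV_NM = 1239.841984

# Boltzmann constant in Hartree/K
KB_HARTREE = 3.166811563e-6
# Boltzmann constant in kcal/mol/K
KB_KCALMOL = 0.0019872041

# 1 a.u. frequency (Hartree) in cm^-1
CM1_PER_HARTREE = 219474.6313632

# atomic mass unit in electron masses
AMU_TO_AU = 1822.888486209

# standard atomic weights (amu), enough for the fixtures used here
ATOMIC_MASSES = {
    "H": 1.00782503, "He": 4.0026, "Li": 7.016, "C": 12.0, "N": 14.0030740,
    "O": 15.9949146, "F": 18.99840, "Na": 22.98977, "Al": 26.98154,
    "Si": 28.0855, "P": 30.97376, "S": 31.9720707, "Cl": 34.96885,
}

ELEMENT_NUMBERS = {
    "H": 1, "He": 2, "Li": 3, "Be": 4, "B": 5, "C": 6, "N": 7, "O": 8,
    "F": 9, "Ne": 10, "Na": 11, "Mg": 12, "Al": 13, "Si": 14, "P": 15,
    "S": 16, "Cl": 17, "Ar": 18,
}
ELEMENT_SYMBOLS = {v: k for k, v in ELEMENT_NUMBERS.items()}
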