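"""Physical constants and element tables used across the package.

Internal unit system: length Å, mass amu, energy kcal/mol.  The derived
time unit sqrt(amu Å² / (kcal/mol)) ≈ 48.89 fs is the DMD time unit (t.u.);
no separate conversion factor is applied anywhere in the dynamics.
"""

import math

# 1 t.u. in seconds: sqrt(amu * Å^2 / (kcal/mol))
_AMU = 1.66053906660e-27          # kg
_KCALMOL = 4184.0 / 6.02214076e23  # J
TU_SECONDS = math.sqrt(_AMU * 1e-20 / _KCALMOL)
TU_FEMTOSECONDS = TU_SECONDS * 1e15  # ≈ 48.89 fs

# Planck constant in kcal/mol · t.u. (for ZPE from frequencies in 1/t.u.)
_H_J_S = 6.62607015e-34
PLANCK_KCALMOL_TU = _H_J_S * 6.02214076e23 / 4184.0 / TU_SECONDS

# Covalent radii (Å) for bond inference; metals are never auto-bonded.
COVALENT_RADII = {
    "H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "S": 1.05,
    "MG": 1.41, "CA": 1.76, "FE": 1.32,
}
METAL_ELEMENTS = {"MG", "CA", "FE", "ZN", "MN", "NI", "CO", "CU", "NA", "K"}

# van der Waals radii (Å) for the stepwise nonbonded stand-in.  Hydrogen is
# deliberately small so H-bonded contacts never sit inside a generic hard core.
VDW_RADII = {"H": 0.40, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80}

ATOMIC_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "MG": 24.305, "CA": 40.078, "FE": 55.845,
}

# Fraction of the severed-bond length at which the saturating hydrogen is
# placed along the original bond direction.
CAP_FACTOR = 0.7052
CAP_H_MASS = 1.008


def covalent_radius(element: str) -> float:
    try:
        return COVALENT_RADII[element.upper()]
    except KeyError:
        raise KeyError(f"no covalent radius tabulated for element {element!r}")


def vdw_radius(element: str) -> float:
    return VDW_RADII.get(element.upper(), 1.70)


def atomic_mass(element: str) -> float:
    try:
        return ATOMIC_MASSES[element.upper()]
    except KeyError:
        raise KeyError(f"no mass tabulated for element {element!r}")
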