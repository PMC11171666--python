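"""Unit system and physical constants.

Internal units throughout the engine: length in angstrom (A), time in
picoseconds (ps), mass in atomic mass units (amu), charge in elementary
charges (e), energy in kcal/mol.  The "internal" energy unit implied by
(amu, A, ps) is amu*A^2/ps^2 = 10 J/mol, hence the 418.4 conversion factor
to kcal/mol.  Piconewtons appear only at the steered-MD / analysis boundary
where spring constants and recorded forces are conventionally quoted in pN.
"""

# 1 kcal/mol expressed in amu*A^2/ps^2 (= 4184 J/mol / 10 J/mol).
KCAL_PER_MOL_TO_INTERNAL = 418.4

# 1 kcal/(mol*A) expressed in pN: 4184 J/mol / N_A / 1e-10 m = 6.94769e-11 N.
PN_PER_KCAL_MOL_A = 69.4769

# Coulomb constant in kcal*A/(mol*e^2), the CHARMM convention.
COULOMB_CONSTANT = 332.0636

# Boltzmann constant in kcal/(mol*K).
KB_KCAL_MOL_K = 0.0019872041

# Atomic masses in amu.
ELEMENT_MASSES = {"C": 12.011, "H": 1.008, "O": 15.999}


def element_of(label: str) -> str:
    """Infer the element from a CHARMM type label or atom name (C*, H*, O*)."""
    e = label[0].upper()
    if e not in ELEMENT_MASSES:
        raise KeyError(f"cannot infer element for label {label!r}")
    return e


def mass_of(label: str) -> float:
    return ELEMENT_MASSES[element_of(label)]
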