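"""Unit conventions.

All energies are held internally in kJ mol^-1 and all distances in Angstrom;
conversion happens once, at file boundaries.
"""

#: CODATA value, exact to double precision for our purposes.
HARTREE_TO_KJ_PER_MOL: float = 2625.4996394799

ENERGY_UNITS = ("hartree", "kJ/mol")


def to_kj_per_mol(value: float, unit: str) -> float:
    """Convert an energy in ``unit`` ('hartree' or 'kJ/mol') to kJ mol^-1."""
    if unit == "kJ/mol":
        return value
    if unit == "hartree":
        return value * HARTREE_TO_KJ_PER_MOL
    raise ValueError(f"unknown energy unit {unit!r}; expected one of {ENERGY_UNITS}")
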