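"""Unit constants and conversions.

Coordinates are carried in Å throughout the package and collective-variable
distances in nm where noted.  Energies appear in two conventions — hill
heights and free-energy surfaces in kJ/mol, dissociation barriers and docking
scores in kcal/mol — so the kJ↔kcal conversion is centralized here and used
everywhere an energy changes convention.
"""

#: Thermochemical calorie: 1 kcal = 4.184 kJ, exactly.
KJ_PER_KCAL: float = 4.184

#: Boltzmann constant in kJ/(mol·K) (CODATA, molar form).
KB_KJ_PER_MOL_K: float = 0.008314462618

#: Å per nm.
ANGSTROM_PER_NM: float = 10.0


def kj_to_kcal(energy_kj: float) -> float:
    """Convert an energy from kJ/mol to kcal/mol."""
    return energy_kj / KJ_PER_KCAL


def kcal_to_kj(energy_kcal: float) -> float:
    """Convert an energy from kcal/mol to kJ/mol."""
    return energy_kcal * KJ_PER_KCAL


def kt_kj(temperature_k: float) -> float:
    """Thermal energy k_B·T in kJ/mol at the given temperature."""
    return KB_KJ_PER_MOL_K * temperature_k
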