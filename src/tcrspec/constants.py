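"""Physical constants and shared conventions.

All free energies are in kcal/mol on the 1 M standard state, so
``dG = R*T*ln(KD)`` with KD in molar and dG < 0 for sub-molar binders.
"""

# Gas constant in kcal/(mol K)
R_KCAL: float = 1.9872e-3

# Default experiment temperature: 25 degrees C
T_STANDARD_K: float = 298.15

# The 20 standard amino acids, alphabetical one-letter codes.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

# Ambiguity / nonstandard one-letter codes that invalidate a scan window.
NONSTANDARD_AA: frozenset[str] = frozenset("BJOUXZ*")


def rt(temperature: float = T_STANDARD_K) -> float:
    """RT in kcal/mol at the given temperature (Kelvin)."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive Kelvin, got {temperature}")
    return R_KCAL * temperature
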