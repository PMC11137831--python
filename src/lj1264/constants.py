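"""Physical constants in the package's working units.

Units throughout: energies kcal/mol, distances Å, charges in units of the
elementary charge e, temperatures K.  These are the AMBER reporting units.
"""

#: Coulomb constant, kcal·Å/(mol·e²).
COULOMB_CONSTANT = 332.0637

#: Universal gas constant, kcal/(mol·K).
GAS_CONSTANT = 1.9872e-3


def kt(temperature: float) -> float:
    """Thermal energy k_B·T (equivalently R·T per mole) in kcal/mol."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return GAS_CONSTANT * temperature
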