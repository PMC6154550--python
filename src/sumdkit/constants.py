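"""Physical constants in the package's unit system (Å, ps, amu, kcal/mol)."""

#: Boltzmann constant, kcal mol^-1 K^-1 (equals the molar gas constant R
#: because energies are per mole throughout).
KB = 0.0019872

#: Default simulation temperature, K.
DEFAULT_TEMPERATURE = 310.0
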