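"""Physical constants in the kcal/mol, Ångström, femtosecond unit system."""

#: Boltzmann constant (= gas constant per mole), kcal/(mol*K)
KB = 1.987204e-3

#: Default system temperature, K
DEFAULT_TEMPERATURE = 298.0
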