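"""Physical constants and packaged defaults (kJ/mol, Å, K)."""

#: Boltzmann constant, kJ/(mol*K)
KB = 0.0083145

#: Default simulation temperature, K
DEFAULT_TEMPERATURE = 300.0

#: Graphene C-C bond length, Å
GRAPHENE_BOND_LENGTH = 1.42

#: Solvent probe radius for SASA, Å
DEFAULT_PROBE_RADIUS = 1.4

#: Lennard-Jones cutoff for protein-surface interactions, Å
DEFAULT_VDW_CUTOFF = 10.0

#: Quasi-uniform sphere points per atom for SASA during sampling / validation
DEFAULT_SASA_POINTS = 240
VALIDATION_SASA_POINTS = 960

#: Width (Å) of the smoothstep point-burial band used by the sampler's
#: energy model (0 = exact binary Shrake-Rupley test)
DEFAULT_SASA_SMOOTHING = 0.3

#: Per-element van der Waals radii used for SASA, Å
SASA_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20}
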