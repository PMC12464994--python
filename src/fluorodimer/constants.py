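"""Physical constants and global conventions."""

#: Gas constant in kcal mol^-1 K^-1.
GAS_CONSTANT_KCAL: float = 1.9872e-3

#: Default sample temperature (K) for all free-energy conversions.
DEFAULT_TEMPERATURE: float = 310.0

#: Sign convention used by every FreeEnergy produced by this package.
#: Position "A" refers to the A-chain conformer of the asymmetric dimer.
SIGN_CONVENTION: str = "positive = distinguished monomer prefers position A"
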