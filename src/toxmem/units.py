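"""Unit conventions and conversion constants.

Internal units are nm (length), ns (time), elementary charge e, and Da.
Diffusion coefficients are *reported* in cm^2/s, the unit the membrane
biophysics literature uses, and converted at the module boundary.
"""

# 1 cm^2/s = 1e14 nm^2 / 1e9 ns
CM2_PER_S_TO_NM2_PER_NS: float = 1.0e5
NM2_PER_NS_TO_CM2_PER_S: float = 1.0e-5

# 1 e*Angstrom = 4.80320 Debye, hence 1 e*nm = 48.0320 D
DEBYE_PER_E_NM: float = 48.0320

# Boltzmann constant in kcal/(mol*K)
KB_KCAL_MOL_K: float = 0.0019872041

# Boltzmann constant in J/K (for hydrodynamic estimates in SI)
KB_J_K: float = 1.380649e-23
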