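"""Physical constants shared by every module.

All coordinates are nanometres, energies kJ/mol, charges elementary
charges, temperatures Kelvin.
"""

#: Boltzmann constant, kJ mol^-1 K^-1 (equals the molar gas constant R).
KB = 0.0083145

#: Molar gas constant, kJ mol^-1 K^-1 (alias of KB on the molar scale).
R_GAS = KB

#: Electrostatic conversion factor e^2/(4 pi eps0), kJ mol^-1 nm e^-2.
F_ELEC = 138.935458

#: Default solvent dielectric for implicit-solvent electrostatics.
EPS_WATER = 78.5

#: Default number of replica-ladder rungs.
N_RUNGS_DEFAULT = 48

#: Default ladder endpoints, K.
T_LADDER_MIN = 315.0
T_LADDER_MAX = 455.8

#: Ensemble analysis temperature, K.
T_ENSEMBLE = 315.0
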