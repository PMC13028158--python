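"""Physical constants and defaults shared across the package.

Energies are carried in kcal/mol throughout; entropies in kcal/(mol*K).
"""

#: Gas constant in kcal/(mol*K).
R_KCAL = 1.9872041e-3

#: Boltzmann constant, J/K (2019 SI exact value).
K_BOLTZMANN = 1.380649e-23

#: Planck constant, J*s (2019 SI exact value).
H_PLANCK = 6.62607015e-34

#: Default temperature, K.
DEFAULT_TEMPERATURE = 298.15

#: Default fraction of the gas-phase entropy retained as solvation entropy.
DEFAULT_ENTROPY_FRACTION = 0.5

#: Default imputed barrier (kcal/mol) for steps without an optimized
#: transition state (fast addition/tautomerization steps).
DEFAULT_IMPUTED_BARRIER = 2.0
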