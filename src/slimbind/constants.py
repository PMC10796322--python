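"""Physical constants and default model constants.

All energies are kJ/mol, entropies J/mol/K, concentrations molar and
temperatures Kelvin unless a function says otherwise.
"""

#: Gas constant, J/mol/K.
R_GAS = 8.314

#: Standard-state concentration, molar.
C_STANDARD = 1.0

#: 25 degC in Kelvin, the reference temperature for reported thermodynamics.
T_REF = 298.15

# Spolar-Record entropy decomposition constants (classic literature values;
# override per analysis when calibrated constants for disordered regions are
# available).

#: Temperature (K) at which the hydrophobic-effect entropy extrapolates to zero.
SR_T_ZERO_HE = 386.0

#: Multiplier relating dCp to the hydrophobic-effect entropy.
SR_HE_COEFF = 1.35

#: Rotational-translational entropy loss on bimolecular association, J/mol/K.
SR_DS_RT = -209.0

#: Conformational entropy change per residue folding upon binding, J/mol/K.
SR_DS_PER_RESIDUE = -23.4

#: Default Monte Carlo draw count for error propagation.
MC_DRAWS = 10_000

#: Default Monte Carlo seed.
MC_SEED = 20240118

#: 15N weight in the combined 1H/15N chemical shift perturbation.
CSP_N15_WEIGHT = 0.154
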