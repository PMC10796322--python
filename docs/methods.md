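# Methods

This note documents the models implemented in `slimbind`, the assumptions
behind them, the defaults that matter, and what the synthetic-data tests
do and do not demonstrate.

## ITC: single-site isotherm and fitting

The forward model (`wiseman_isotherm`) is the one-set-of-sites binding
isotherm. After injection *i* the total macromolecule and titrant
concentrations in the cell follow the perfusion (overflow) bookkeeping of
fixed-volume instruments,

    Mt_i = M0 (1 − dV_i/2V0) / (1 + dV_i/2V0)
    Xt_i = X0 (dV_i/V0) / (1 + dV_i/2V0),

where dV_i is the cumulative injected volume. The bound-titrant
concentration solves the mass-balance quadratic
[RL]² − (N·Mt + Xt + Kd)[RL] + N·Mt·Xt = 0, and the injection heat is the
change in bound-state heat content, corrected for the heat carried out in
displaced volume, plus a constant per-injection dilution offset. A
no-overflow variant (growing cell volume) is available via
`overflow=False`; there the heat content tracks total moles bound,
`[RL]·ΔH·(V0+dV)`.

`ITCModel.fit()` runs bounded nonlinear least squares over
(N, log₁₀Kd, ΔH, offset) with multi-start over the Kd decade, residuals
normalized by the heat scale (injection heats are ~µJ, i.e. ~1e-9 kJ, and
unnormalized costs would underflow optimizer tolerances). Standard errors
come from the jacobian covariance; ΔG = RT ln Kd and −TΔS = ΔG − ΔH are
derived with linear propagation. The first (small) injection is discarded
by default, matching standard practice. A c-value ([cell]/Kd) outside
[1, 1000] annotates the result as poorly designed for Kd determination;
fits whose signal is indistinguishable from the offset are flagged
unidentifiable rather than returned silently.

Constants: R = 8.314 J/mol/K, standard state 1 M, 25 °C = 298.15 K. Kd is
molar everywhere inside the library.

## ΔCp and the Spolar-Record decomposition

`DeltaCpModel` fits ordinary least squares of ΔH versus T (slope = ΔCp)
and of −TΔS versus T, reporting slopes with standard errors and
t-based 95% confidence intervals.

`spolar_record_id` decomposes the association entropy at temperature T:

    ΔS_HE   = c · ΔCp · ln(T / T_HE)          (hydrophobic effect)
    ΔS_conf = ΔS_assoc − ΔS_HE − ΔS_RT        (conformational remainder)
    R_th    = ΔS_conf / ΔS_residue            (residues folding on binding)

Defaults are the classic literature constants — T_HE = 386 K, c = 1.35,
ΔS_RT = −209 J/mol/K, ΔS_residue = −23.4 J/mol/K — and all are keyword
arguments, because calibrations adapted to intrinsically disordered
ligands differ and should be supplied explicitly when available. Passing
`None` for a constant raises an error naming it. Uncertainty is propagated
by Monte Carlo (default 10,000 Gaussian draws, fixed seed 20240118); the
decomposition is linear in its inputs, so the output SD scales exactly
linearly with the input SEs.

## Branched cis/trans isomer binding

The model has one receptor and a ligand whose free pool interconverts
between trans and cis isomers with equilibrium constant K_eq (fraction cis
f = K_eq/(1+K_eq)); each isomer binds with its own K_d, and the two bound
states do not interconvert directly. Free-pool interconversion is assumed
fast relative to the titration timescale, which makes the apparent
constant the population-weighted harmonic mean:

    1/K_d,app = f_cis/K_d,cis + (1 − f_cis)/K_d,trans.

Exchange NMR measures per-pool bound fractions p (the fraction of all
cis, or all trans, molecules that are bound). At a common free-receptor
concentration [R], each pool obeys p/(1−p) = [R]/K_d, so the bound-
fraction odds fix the ratio K_d,trans/K_d,cis = odds_cis/odds_trans
independently of [R]. Combining the ratio with the harmonic relation
yields both constants in closed form; this ratio-plus-harmonic
construction is the unique solution consistent with both observables.
Uncertainties are Monte Carlo. `solve_equilibrium` provides the exact
forward mass balance (bracketed 1-D root in free receptor) for
cross-checks; it conserves mass to ~1e-14 relative.

Interpretation note: bound fractions are per isomer pool, not fractions
of the total ligand. At the nominal exchange-sample composition (500 µM
ligand, 5% receptor) the forward solver gives per-pool bound fractions
within one percentage point of typical measured values; exact agreement
requires the true receptor ratio, which is only nominally known.

## Effective concentration and avidity

For a secondary motif tethered at linker length L (residues), the
effective concentration is the empirical power law Ce = a·L^b with
default b = −1.5 (random-coil-like scaling) and a calibrated so that
Ce(12.5) = 9 mM. Both are assumptions exposed as `LinkerModel` fields, not
measurements; the SD comes from Monte Carlo over the linker-length SD.
Secondary-site saturation is Ce/(Ce+K_d), and the independent-site avidity
prediction for the bivalent constant is K_d,primary/(1 + Ce/K_d,secondary).
The avidity prediction deliberately ignores linker interactions and
inter-site cooperativity; a measured bivalent affinity tighter than the
prediction indicates exactly those contributions.

## CEST: Bloch-McConnell simulation and fitting

`simulate_cest` builds, for each carrier offset, the full (3N+1)-dimension
generator over (Mx, My, Mz) of all N states plus a constant term: per-state
transverse relaxation R2 and resonance offset, RF nutation ω₁ = 2πB₁ about
x, longitudinal relaxation R1 toward the equilibrium polarization p_i, and
first-order exchange obeying detailed balance (pair rate k_ex split as
k_ij = k_ex·p_j/(p_i+p_j)). Magnetization starts at thermal equilibrium
and evolves for the saturation time by `scipy.linalg.expm`; I/I0 is the
observed state's Mz divided by its equilibrium value. A step-wise ODE
integration (`simulate_cest_ode`, LSODA at rtol 1e-10) is retained purely
as an independent cross-check; the two agree to <1e-6. Exchange
topologies are restricted to a star on the observed free state —
bound-bound exchange is excluded by construction. B₁ is treated as ideal
(no inhomogeneity distribution).

`CESTModel` fits residue groups globally: minor-state populations and
exchange rates are shared across the group, each residue carries its own
major-state offset and bound-state shift difference(s) Δω. Profiles are
screened before fitting: after light smoothing, a profile must show at
least two dips with prominence above 3× the noise SD (the major dip plus
a minor dip); profiles failing this are excluded as "no exchange" —
prominence rather than raw depth is used because direct-saturation tails
of the major dip are wide at strong B₁. Relaxation rates default to fixed
shared values (R1 = 1.5 s⁻¹, R2 = 10 s⁻¹) and can be fitted as shared
nuisances with `vary_relaxation=True`; they are kept fixed by default
because with few B₁ fields they trade against k_ex. For three-state fits
the ratio of the two minor populations can be pinned
(`fix_minor_ratio`), e.g. from an independently measured isomer
equilibrium, to reduce degeneracy. Initial shift guesses come from dip
positions ranked by depth; when the two minor states have nearly equal
populations this ranking can permute state labels between residues —a
known limitation — so fits are best run with distinguishable minor
populations or a pinned ratio.

Default simulated designs use three B₁ fields (25, 12.5, 6.25 Hz), 0.4 s
saturation and 81 offsets over ±12 ppm at a ¹⁵N frequency of 81.08 MHz.

## Stopped-flow kinetics

Association traces under pseudo-first-order excess relax as single
exponentials with k_obs = k_on[R] + k_off. Traces are fitted individually
(baseline + ΣA·exp(−kt), rates sorted descending; the first 2 ms are
discarded as instrument dead time, configurable); per-condition replicate
rates are summarized by fitting a cumulative Gaussian Φ((x−µ)/σ) to their
empirical CDF. k_on is the weighted linear slope of k_obs versus
concentration, with a quadratic-term lack-of-fit F-test (α = 0.05): a
significant test flags the series as non-linear and the slope as not a
valid k_on — the honest outcome for mechanisms with additional steps.
Dissociation by competitive displacement is fitted per phase as
k_obs(c) = k_off − A·exp(−c/c₀), reporting the asymptote; a fitted c₀
beyond the titrated range triggers a no-plateau warning. The specific
three-parameter asymptotic form is an interpretation (only "exponential
decay asymptote" is conventionally stated); it nests the constant series
(A = 0).

## NMR titrations

Combined CSPs are sqrt(δH² + (0.154·δN)²). Per-residue K_d fits use the
exact single-site quadratic with ligand depletion, because receptor
(~100–150 µM) is comparable to site affinities; the weak-binding linear
limit falls out naturally when K_d greatly exceeds the ligand range.
Residues whose CSP never exceeds 0.01 ppm are flagged unbound. Affinity
regimes are assigned by exact 1-D two-means clustering on log₁₀K_d
(the best split of the sorted values — exact for one dimension).
Intensity tracing reports I/I₀ per residue and flags residues whose final
relative intensity falls below 0.3 as exchange-broadened. Significance
tiers for CSP maps default to 0.1/0.2 ppm.

## Tiling screens

Sequences are tiled with 40-residue windows at 10-residue steps,
1-based inclusive; when the last regular window misses the C-terminus an
extra C-terminally anchored tile is added so every residue is covered.
Tile counts are normalized to fractions within each tile before the dot
product with the bin medians — read-depth differences between tiles are
sequencing depth, not activity — and scores are z-normalized across the
tiles of the input screen (the z-reference is per screen). Residue scores
average all covering tiles; AD regions are maximal runs of residues whose
*every* covering tile clears the threshold, which is conservative by
construction (a strict subset of any-tile calls).

## Synthetic data

Generators mirror the real designs: ITC titrations of 18 × 2 µL plus a
discarded 0.5 µL initial injection at 15 µM cell and 10× syringe; CEST at
three B₁ fields with Gaussian intensity noise (default 1%); stopped-flow
with ≥ 20 replicate traces per condition and 1% amplitude noise; HSQC
titrations at constant 125 µM receptor with two affinity regimes (300 µM
and 4.5 mM defaults); multinomial screens whose bin probabilities follow
a Gaussian kernel centred monotonically in true activity, at 2000 reads
per tile. Noise is Gaussian throughout except multinomial counts. Every
generator is bit-reproducible under its seed and serializes its
generating parameters (`GroundTruth`).

What the generators do *not* emulate: baseline drift and injection-to-
injection correlation in ITC; B₁ inhomogeneity, peak overlap and
lineshape distortions in CEST; photobleaching and mixing artefacts in
stopped-flow beyond a hard dead-time cut; assignment errors and peak
overlap in titrations; PCR/sorting biases in screens. Recovery tests on
synthetic data therefore demonstrate the correctness and statistical
calibration of the estimators under their stated noise models, not
robustness to instrument systematics.

## Numerical choices and problem sizes

Optimizers are `scipy.optimize.least_squares`/`curve_fit` with bounds and
problem-scaled residuals; ITC fits multi-start across the Kd decade; CEST
fits transform k_ex logarithmically. Test and verification problem sizes
are chosen to exercise the estimators well while keeping the default
suite fast: 100-replicate ITC noise ensembles, 100 random exchange models
for the propagator cross-check (5 offsets each), single-group CEST fits
with three residues and three B₁ fields, 20-replicate kinetic designs,
and 1000-draw coverage simulations for linear-fit confidence intervals.
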