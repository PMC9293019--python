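# Methods

## The dual-cycle microkinetic model

A dimeric catalyst with two secondary-amine (pyrrolidine) active sites is
modelled as two catalytic cycles, A and B, sharing one catalyst pool. Each
cycle is a loop of elementary steps:

1. **Acid activation.** `cat + H⁺(reservoir) ⇌ catH_X`. Both sites are
   assumed equally basic, so the default forward and reverse constants are
   identical for A and B (asymmetry is configurable); the A:B outcome then
   emerges from the landscape energies, not from the partition step.
2. **Enamine formation.** `catH_X + ketone(reservoir) ⇌ EN_X,conf`, one
   species per conformer (distal: enamine C=C away from the carboxamide,
   |ω| ≥ 90°; proximal otherwise).
3. **Conformer interconversion.** `EN_X,distal ⇌ EN_X,proximal`, fast by
   default (Curtin–Hammett regime), lowerable to the frozen-conformer limit.
4. **Electrophile association.** `EN + E ⇌ RC`, one reactive complex per
   landscape point.
5. **C–C bond formation.** `RC → INT`, irreversible, one reaction per
   transition state; this is the only step whose rate comes from the
   quantum-chemical landscape, `k = (k_B T/h)·exp(−(G_TS − G_RC)/RT)`.
6. **Hydrolysis / product release.** `INT → cat + P_channel`, irreversible,
   regenerating the free catalyst.

Steps 1–4 are not resolved by the electronic-structure landscape; they are
lumped with fast default constants (10³ s⁻¹ or M⁻¹s⁻¹; conformer flips
10⁶ s⁻¹). Their *reverse* constants are set by detailed balance against the
relative Gibbs energies, with the landscape zero at the reference enamine
plus free electrophile and the activated catalyst placed at 0 kcal/mol by
default. Because the entire pre-C–C network is then thermodynamically
consistent, the fast-pre-equilibrium limit reproduces the analytic
Curtin–Hammett ratio `exp(−ΔΔG‡/RT)` — the engine's oracle test — to the
integrator tolerance (observed agreement ~10⁻¹³ relative on the two-channel
benchmark).

**Pseudo-first-order reservoirs.** The ketone (60:1 excess in the aldol
kinetics, 8:1 in the Michael case) and the acid additive are clamped
reservoir species at unit activity: they enter rate laws and composition-tag
balances but are not depleted. Effective first-order "enamine formation"
constants therefore absorb the excess-nucleophile concentration.

**Flux attribution.** One auxiliary ODE state per stereochannel integrates
that channel's instantaneous C–C rate, so per-channel fluxes are exact to
integrator tolerance and the A:B partition is well defined even when
channels share a product. dr sums fluxes by diastereomer class
(anti = {(2R,1'S),(2S,1'R)} for the aldol; the same configurations are the
syn class in the Michael family); ee is evaluated on the
(2R,1'S)/(2S,1'R) pair with (2R,1'S) positive.

## Parameters that matter

| parameter | units | default | why |
|---|---|---|---|
| temperature | K | 298.15 | standard conditions; configurable per landscape |
| k_protonation, k_enamine, k_hydrolysis | s⁻¹ | 10³ | fast vs. typical C–C rates (s⁻¹ scale at ~17 kcal/mol barriers) |
| k_conformer | s⁻¹ | 10⁶ | enforces the Curtin–Hammett regime by default |
| k_association | M⁻¹s⁻¹ | 10³ | diffusion-limited on the model's time scale |
| conc_electrophile | M | 0.10 | limiting reagent, 1 equiv |
| conc_catalyst | M | 0.03 | 30 mol% loading of the kinetic experiments |
| rtol / atol | – | 10⁻¹⁰ / 10⁻¹³ | see numerical choices |

Physical constants: k_B = 1.380649×10⁻²³ J/K, h = 6.62607015×10⁻³⁴ J·s
(CODATA, exact), R = 1.987204×10⁻³ kcal mol⁻¹ K⁻¹; transmission coefficient
fixed at 1.

## NMR kinetic fitting

The log-ratio transform anchors y(t₀) = 0 by construction; the regression
nevertheless carries a free intercept by default, which absorbs integration
error in the t₀ spectrum (an origin-anchored mode is provided). k_obs is
the unweighted mean of the per-signal slopes; the quoted error is the
cross-signal standard deviation (ddof = 1), or the regression slope
standard error when only one signal is available. Points whose reference
integral falls below 10⁻⁶ of its maximum are excluded. Unweighted ordinary
least squares is used throughout; with ~2% multiplicative integral noise
the log transform makes the noise additive and nearly homoscedastic, so
weighting would change little.

## What the synthetic data emulate — and what they do not

- **Kinetic traces**: exact single-exponential decay of three signal
  integrals (levels 2:2:1, mimicking the ortho/meta/para fluorine counts of
  a pentafluorophenyl group) against a constant reference, with
  median-unbiased multiplicative lognormal noise (log ε ~ N(0, σ)); default
  grid 12 points over 3000 s. Real spectra add baseline/phase error,
  signal-dependent integration error and reference drift — recovery results
  on synthetic traces bound estimator bias, not instrument systematics.
- **Landscapes**: the dual-cycle presets have the right topology (two
  cycles, distal/proximal conformers, four stereochannels) but illustrative
  round energies chosen once; they are synthetic stand-ins, not
  electronic-structure results, and the simulated dr/ee/A:B for them are
  demonstrations of the machinery. The two-channel preset with
  ΔΔG‡ = 1.447 kcal/mol is the analytically calibrated benchmark
  (RT·ln(92/8) at 298.15 K → dr 92:8).
- **Conformer ensembles**: two dihedral clusters (near 0° and 180°,
  σ = 15°) with half-normal within-cluster energy spread; with equal widths
  the designed Boltzmann split equals the two-state value, which the
  analysis recovers within Monte-Carlo error.

## Numerical choices

- LSODA integration with rtol 10⁻¹⁰ / atol 10⁻¹³. The tighter-than-usual
  defaults keep linear invariants (catalyst and electrophile composition
  totals) conserved to better than 10⁻⁸ relative across the stiff rate
  spread (10⁶ s⁻¹ flips vs. ~10⁻² s⁻¹ effective consumption); at
  rtol 10⁻⁸ the drift can reach ~2×10⁻⁸.
- Simulation ends at a fixed t_end; `selectivity` warns below 99%
  electrophile conversion rather than event-detecting completion.
- Negative concentrations beyond 10⁻¹² of the initial maximum abort with
  the last valid state; smaller round-off is clipped to zero.
- Dihedral classification folds any angle to [0°, 180°]; the |ω| = 90°
  boundary is assigned to distal (ties-to-distal convention; only the ≈0°
  and ≈180° extremes are physically meaningful).
- Boltzmann weights use the max-shift trick; weight sums are exact to
  10⁻¹².
- ee predictions of the additive model use exact arithmetic means, rounded
  to integers only at report time.

## Design choices where the design was open

- **Precursor matching.** A transition state is paired with the reactive
  complex of its own cycle and conformer, preferring an exact stereo-label
  match and falling back to an unlabelled complex; ambiguity is an error.
  The builder accepts any channel set, since the full enumeration of
  pathways per cycle is system-dependent.
- **Reversibility.** Everything before the C–C step is reversible (with
  detailed-balance reverse rates); C–C formation and hydrolysis are
  irreversible. This is the minimal scheme under which selectivity is
  barrier-controlled and products accumulate.
- **Attribution by flux, not pools**, as described above.
- **Per-channel product species** keyed by (cycle, face pair,
  configuration), so terminal pools and integrated fluxes agree by
  construction — a useful internal cross-check.

## Known limitations

- No tunneling, variational or transmission corrections; rates are plain
  transition-state theory on supplied Gibbs energies.
- Acid/base speciation is collapsed into a unit-activity proton reservoir;
  strongly acid-dependent kinetics are outside the model.
- Enamine formation and hydrolysis rates are lumped guesses; absolute time
  scales are therefore only indicative, while selectivities (the model's
  purpose) are insensitive to them in the fast-lumped-step regime.
- No stochastic (low-copy-number) simulation and no sensitivity analysis
  beyond what finite differences on the rate constants would give.
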