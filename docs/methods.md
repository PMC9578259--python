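# Methods

## Conservation framework

All stoichiometric reasoning rests on two balances. Carbon is counted from
elemental formulas; electrons are counted by degree of reduction,

γ = 4·C + 1·H − 2·O − 3·N  (electron-mol per mol),

the convention for ammonia as nitrogen source, under which a Cmol of yeast
biomass CH₁.₈O₀.₅N₀.₂ carries γ_x = 4.2 and corresponds to 26.4 g dry
weight. Redox cofactors are bookkeeping tags outside the element balances:
NADH carries 2 electron-mol, ATP none. This is deliberate — the pathway
half reactions are written without water, protons or phosphate, so they
are hydrogen/oxygen-unbalanced by construction, while carbon and electrons
must (and do) close. A reaction is accepted as balanced when both
imbalances, normalized by the largest stoichiometric coefficient, are
below 1e-9.

ATP is tracked as net ATP only (no ADP/Pi pool), matching how the pathway
lumps are written; nothing downstream needs the adenylate pool itself.

## Redox-neutral combination of half reactions

Given half reactions with NADH coefficients n_i, the combiner finds
non-negative weights w with Σ w_i·n_i = 0. For two reactions with
opposite-sign NADH this direction is unique, (|n₂|, |n₁|); a single
already-neutral reaction passes through unchanged; more than two reactions
leave free directions, which is reported as an ambiguity together with a
nullspace basis rather than silently resolved. The net reaction is
computed in exact rational arithmetic (coefficients rationalized with
denominators ≤ 1000) and rescaled to the smallest integer coefficients;
if rationalization fails, the fallback is normalization per mole of a
designated substrate. Applied to the glycolytic (per 3.5 sorbitol,
+3.5 NADH, +7 ATP) and PRK–RuBisCO (per 2.5 sorbitol, −3.5 NADH) lumps
this yields 6 sorbitol → 13 ethanol + 10 CO₂ + 7 ATP exactly.

## The core network model

Per operating mode the network holds:

* substrate entry and fermentative catabolism — for sorbitol, an
  energy-independent facilitator plus NAD⁺-dependent sorbitol
  dehydrogenase (sorbitol → fructose + NADH) followed by fructose
  fermentation (fructose → 2 ethanol + 2 CO₂ + 2 ATP net, counting the
  fructokinase and phosphofructokinase investments against the four
  payoff ATP); for glucose, the canonical 2-ethanol/2-ATP lump;
* one redox sink: the native glycerol branch
  (½ hexose + NADH + ATP → glycerol) in the reference mode, or the
  PRK–RuBisCO bypass (per mol sorbitol: +1.4 NADH consumed, 2.4 ethanol,
  1.2 CO₂, zero net ATP — the PRK ATP investment is internal to the lump).
  The glucose-entry bypass variant is the sorbitol lump minus the
  dehydrogenase NADH, re-closed on carbon and electrons
  (glucose + 0.4 NADH → 31/15 ethanol + 28/15 CO₂). Exactly one sink is
  active per solve; a mixed-sink mode would leave a free flux direction
  and is therefore not offered;
* a biomass equation producing 1 g dry biomass, with substrate and CO₂
  coefficients derived from the two conservation laws given the ATP
  demand n_ATP (mmol/g), surplus-NADH yield n_NADH (mmol/g), γ_x and the
  Cmol mass — so it is balanced by construction and infeasible parameter
  combinations (negative coefficients) are rejected rather than clipped;
* a maintenance ATP drain with flux fixed at m_ATP (mmol g⁻¹ h⁻¹).

At a given μ the biomass flux is fixed at μ and the maintenance flux at
m_ATP; closing the NADH, ATP and intermediate balances leaves a square
linear system in the remaining fluxes, solved with LAPACK. Fluxes below
−1e-9 raise an infeasibility error; smaller negatives are clipped to
zero. The growth-free catabolic limits (theoretical maximum ethanol and
ATP yields) are solved separately in exact Fraction arithmetic, giving
13/6 and 7/6 for the combined sorbitol pathway and 2 and 2 for glucose;
the maintenance threshold is m_ATP divided by the ATP yield
(6/7 ≈ 0.857 mmol g⁻¹ h⁻¹ at m_ATP = 1).

### Biomass parameter defaults and calibration

The biomass equation's coefficients are not printed anywhere usable, so
the defaults are order-of-magnitude anchors: n_ATP = 62.5 mmol/g
(≈ 16 g biomass per mol ATP, typical of anaerobic glucose-limited yeast),
n_NADH = 10 mmol/g (the order of observed wild-type glycerol-per-biomass
ratios), m_ATP = 1 mmol g⁻¹ h⁻¹. `calibrate_biomass_params` re-anchors
them to data: n_NADH is the observed glycerol/biomass ratio (in the
reference strain every surplus NADH makes one glycerol, so the identity is
exact), and n_ATP is solved in closed form so the reference-mode
prediction reproduces the observed biomass yield at the observed dilution
rate. Calibrated against the reference chemostat (glycerol/biomass
8.1 mmol/g, Y_x 14.2 g/mol at D = 0.025 h⁻¹) this gives
n_ATP ≈ 70 mmol/g, and the resulting sorbitol yield curve stays above the
glucose ceiling of 2 mol/mol for all μ ≤ 0.1 h⁻¹.

Consequently the model reproduces the *shape* and the exact μ → 0 limits
of the published yield/rate curves, not the unpublished point values. The
42 %-less-ATP and 71 %-higher-flux comparisons are ATP-stoichiometry
arithmetic (1 − (7/6)/2 and 2/(7/6) − 1) and are computed as such; at
finite μ the lumped network's biomass-yield ratio deviates from the pure
ATP ratio because biomass carbon draw and the glycerol sink's ATP cost
enter the substrate balance.

## Quantitative physiology

* Growth rate: OLS slope of ln(biomass) vs time, requiring at least 7
  samples; the exponential window is user-supplied or auto-selected as
  the positive-slope sliding window (length ≥ 7) maximizing R². The 95 %
  CI comes from the regression standard error.
* Batch yields: slopes of product (or biomass) against molar substrate
  consumption over the window, so constant offsets cancel. The combined
  substrate yield uses summed molar consumption of glucose and sorbitol.
* Chemostat rates: q_i = D·(c_in − c_out)/(M_i·Cx)·1000, sign-flipped for
  products; per-biomass consumption is q/D (an exact identity). Replicates
  are reported both per replicate and pooled (mean concentrations first),
  since the two averaging orders differ on real data.
* Detection bounds: concentration differences below 0.3 g/L (batch) or
  0.5 g/L (chemostat, feed-relative) are reported as censored upper
  bounds, never as zeros.
* Electron recovery: 100 · Σ(γ·Δn)_products+biomass / Σ(γ·Δn)_substrates.
  CO₂ contributes nothing (γ = 0), which is why this check is robust to
  CO₂-enriched inlet gas, unlike a carbon recovery — the package
  deliberately computes no carbon recovery.
* Wash-in classification: post-event residuals are compared to
  c(t) = c_in − (c_in − c_t0)·e^(−D·(t−t0)). Mean relative deviation
  below the tolerance (default 0.05) → "washed-in" (consumption lost);
  a signed deviation below −tolerance → "consuming"; otherwise
  "partial". At least 3 post-event samples are required.
* Ethanol evaporation: a single first-order stripping constant k (1/h),
  corrected(t) = measured(t) + k·∫measured dt (trapezoidal); default 0.

## Synthetic data

The generators emulate the study conditions: anaerobic batches on
20 g/L glucose + 30 g/L sorbitol growing exponentially until glucose
exhaustion, with product trajectories linear in biomass formed (apparent
ethanol yield on glucose, glycerol and sorbitol coupled per g biomass);
and chemostats at D = 0.025 h⁻¹ on 10 + 10 g/L feed, with biomass held at
its steady-state value and each residual concentration following
dc/dt = D(c_in − c) − q·Cx with piecewise-constant q. The chemostat is
solved analytically segment by segment (no integrator tolerances), so an
uptake-cessation event produces the wash-in closed form exactly and
concentrations are continuous across events. The engineered-strain
factory closes the electron balance when choosing the ethanol production
rate, so noise-free output has a degree-of-reduction recovery of exactly
100 %; its conditions (Cx 1.18 g/L, sorbitol uptake 0.675 mmol g⁻¹ h⁻¹)
leave ≈ 4.2 g/L residual sorbitol.

Noise is multiplicative lognormal per observation (default σ = 0.02,
chosen to reproduce the spread of replicate culture measurements
qualitatively), applied after the deterministic trajectory; the same seed
gives bit-identical series. What the generators do *not* emulate: lag
phases, substrate-affinity kinetics (uptake is stoichiometric, not
Monod), gas-phase CO₂ transfer, evolutionary loss of the bypass, and
autocorrelated measurement error. Passing recovery tests therefore
demonstrate estimator correctness under the assumed measurement model,
not robustness to those real-data features.

## Numerical choices

* Exact paths (half-reaction combination, catabolic yields) use stdlib
  Fractions; an independent sympy rational solve serves as the test
  oracle for the network solve (agreement to 1e-12).
* Balance tolerance 1e-9 on normalized coefficients; flux non-negativity
  tolerance 1e-9; infeasible yield-curve rows are flagged per row, not
  fatal.
* Test problem sizes are kept small (≤ 12-point batches, ≤ 121-point
  chemostats, 100-seed Monte-Carlo loops), which the estimators' closed
  forms make statistically sufficient; the whole suite runs in a few
  seconds.

## Known limitations

The network is a lumped core model: no genome-scale reconstruction, no
thermodynamics, no proton/charge balancing, no competitive uptake
kinetics between glucose and sorbitol, and no phosphoketolase-type
alternative bypass. Biomass-equation coefficients are calibrated, not
measured, so absolute biomass yields carry that parameterization.
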