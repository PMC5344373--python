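# Methods

## Scope and approach

The package infers metabolic exchange fluxes in a two-species anaerobic
batch co-culture from community-level data by embedding per-species
stoichiometric models in a dynamic flux balance analysis (dFBA).  Both
species are represented by coarse-grained models: pathway segments are
lumped into single net reactions, and ATP, NAD(H) and ferredoxin are
element-free bookkeeping tokens whose steady-state rows enforce energy
and redox closure.  Coarse-graining keeps the degrees of freedom close
to what batch data can actually constrain; the SBML reader keeps the
door open for genome-scale replacements without code changes.

## Species models

**Fermenter (*C. acetobutylicum* surrogate, 18 reactions).**
Glycolysis (glucose → 2 pyruvate + 2 ATP + 2 NADH), pyruvate:ferredoxin
oxidoreductase, ferredoxin hydrogenase, reversible NADH↔ferredoxin
transhydrogenation, acetate branch (+1 ATP per acetyl-CoA), butyrate
branch (2 acetyl-CoA + 2 NADH, +1 ATP), ferredoxin-dependent nitrite
reductase (NO2⁻ + 6 e⁻ → NH4⁺, plus a 0.1 ATP transport cost),
nitrogenase (N2 + 8 e⁻ + 16 ATP → 2 NH4⁺ + H2, textbook stoichiometry),
an ATP-hydrolysis valve, biomass, and exchanges.  The NH4⁺ exchange is
reversible (ammonification allowed).  The small ATP cost on the nitrite
route makes NO2⁻ strictly growth-penalising relative to NH4⁺, which is
the behaviour of the full metabolic network; without it the
unconstrained optimum is degenerate in its N source.

**Respirer (*W. succinogenes*, 8 reactions).**  H2 uptake, formate
oxidation (closed by default — no formate is observed), NO3⁻ uptake,
NO3⁻ → NO2⁻ respiration yielding 1.0 ATP per NO3⁻ (literature-derived
electron-transport yield; config-exposed), NO2⁻ → NH4⁺ reduction,
acetate uptake (carbon source), NH4⁺ uptake, biomass.  The nitrite
ammonification step is kept open because it is the organism's only
assimilatory nitrogen route when no NH4⁺ is supplied; growth-maximising
FBA never uses it dissimilatorily (it yields no ATP and burns H2), so
with NH4⁺ present its flux is zero, consistent with the high-nitrate
regime in which bulk NO2⁻ reduction is suppressed.

**Biomass.**  Both species use a CH1.8O0.5N0.2 composition: 40.607 mmol
C and 8.121 mmol N per gDW.  Carbon enters as pyruvate (fermenter,
13.536 mmol/gDW) or acetate (respirer, 20.304 mmol/gDW).  The remaining
demands — fermenter 42.67 mmol ATP and 2.64 mmol NADH per gDW, respirer
200 mmol ATP per gDW — are fitted quantities (see *Parameter
provenance*).

## Element audit

`check_element_balance` verifies conservation of every element except H
and O: free exchange of protons and water (not modelled explicitly) can
close any H/O imbalance, so only C, N, S, P… are conserved quantities.
Exchanges and the biomass drain cross the system boundary and are
reported as uncheckable rather than silently passed, as is any reaction
touching a metabolite of unknown composition.

## Dynamics

Fixed-step explicit Euler, default dt = 0.01 h over 30 h.  At each step,
each species' uptake bounds are set from Michaelis–Menten kinetics at
the current concentrations, capped by pool availability (a species
cannot withdraw more within one step than the pool holds; joint
overdraw by several species is resolved by proportional fair-sharing
and a re-solve).  Each species' biomass flux is then maximised by FBA
with parsimonious (L1-minimal) tie-breaking, making the reported flux
vectors unique and reruns bitwise reproducible.  An infeasible FBA
means dormancy: zero growth, zero fluxes, no maintenance and no death
term — which is exactly how the respirer sits flat in the NH4-only and
N2 regimes.  An adaptive RK45 mode exists but is not the default, since
adaptive integration of an LP-embedded right-hand side is solver-order
dependent.  Gases (H2, CO2) are tracked as a single well-mixed pool in
culture-volume concentration units; no Henry-law partitioning.

Halving dt changes final biomasses by well under 0.5%; carbon closes to
~1e-5 relative over a full batch (the Euler update is linear in the
balanced LP fluxes, so conservation is exact up to LP tolerance).

## Condition presets

Media recipes converted to mM: glucose monohydrate 0.59 g/L → 2.977 mM,
NH4Cl 0.25 g/L → 4.674 mM, NaNO3 0.85 g/L → 10.00 mM.  Nitrogen regimes:
`NH4_NO3`, `NH4`, `NO3`, `N2` (N2 as a non-limiting pool; elsewhere no
dissolved N2 is supplied, a proxy for nitrogenase repression by fixed
nitrogen).  The optional `carry_over_no3` parameter adds residual
nitrate from the pre-culture to any condition.

Two further carry-over seeds are package constants: 0.05 mM NO2⁻ and
0.05 mM acetate arrive with the 1:100 inoculum from the actively
respiring/fermenting pre-culture.  They are not cosmetic: at t = 0 the
NO3-only condition is a strict mutualistic deadlock (the fermenter has
no nitrogen until the respirer makes NO2⁻; the respirer has no energy or
carbon until the fermenter makes H2 and acetate), and a dFBA with
parsimonious fluxes and no maintenance cannot escape it.  The seeds are
consumed within hours and are three orders of magnitude below the final
pools, so cumulative yields are unaffected.  Similarly, the inoculum
carries the species at their balanced-growth composition (0.002 and
0.00018 gDW/L), reflecting the serially pre-adapted co-culture from
which the batches are started; a 1:1 inoculum would spend most of the
batch converging to the balanced ratio.

## Parameter provenance

The published fitted parameter table for this system (kinetics, ratio
constraints, respirer biomass composition) is not reproduced in the
available text, so the defaults here were re-derived by the same
procedure the original analysis used — adjusting them until the
simulated co-culture reproduces the experimentally inferred outcomes —
done in closed form on the surrogate's linear balances rather than by
eye.  Per mol glucose the fermenter's balances give

    Y (c_ATP + c_pyr) = 4 − b − 0.1 n          (ATP)
    h = 4 − 2b − (c_pyr + c_NADH) Y − 3n       (ferredoxin electrons)
    n (1 + r_NH4/NO2) = c_NH4 Y                (nitrogen)

with Y biomass yield, b butyrate, h H2, n NO2⁻ per glucose.  Anchoring
these to the inferred H2 yields (1.10 and 0.94 mol/mol in the NH4+NO3
and NO3 regimes), the fitted-to-optimal growth ratios (87% and ~94%)
and the optimal-scenario H2 increases (+159%, +23%) fixes the ATP and
NADH biomass demands and the per-condition ratio constraints
(butyrate/acetate = 2.67, 4.27, 0.222, 2.0 and NH4⁺/NO2⁻ = 0.64 for
NH4_NO3; all in `syntroflux.config`).  Glucose Vmax varies by condition
(5.0, 5.5, 5.0, 3.0 mmol·gDW⁻¹·h⁻¹), Km 0.2 mM, giving fermenter growth
rates of ~0.25–0.34 h⁻¹.  Respirer kinetics (H2 Vmax 80, Km 1 µM; NO3⁻
Vmax 80; acetate Vmax 15) reflect the high specific H2-oxidation
capacity and sub-micromolar H2 affinity of hydrogenotrophs; the tight
H2 Km is also what lets the H2 pool servo the two growth rates into
balance within ~10 h.  The model structure is identical across
conditions; only parameters change.

## Fitting

The loss is a weighted sum of squared standardized residuals over
observation channels (standardized by the channel's noise sd, or by its
range when unknown); OD and concentrations on a linear scale, qPCR
copies on log10.  Optimisation is multi-start Nelder–Mead over the
parameter box with seeded Latin-hypercube start points; ratio
parameters are searched in log space to preserve positivity.  "Agreed
most with the data" thereby becomes an explicit, reproducible
objective.  Recovery tests use a fermenter monoculture in the NH4
regime (12 h, dt = 0.1 h, plain LP mode — the monoculture optimum is
unique, so the parsimonious stage is unnecessary): noise-free data
return glucose Vmax and Km within 5%; with 5% multiplicative noise and
triplicates the median |relative error| of Vmax over 20 seeded repeats
is well under 15%.

## Synthetic data

The generator maps a noise-free simulation through the observation
model (OD600 = 2.5·ΣX; qPCR = 1e12 genome-corrected copies per gDW;
metabolites direct), then applies per-channel noise — additive Gaussian
for HPLC/GC/OD (defaults: 2%-of-scale for metabolites, 0.01 OD),
multiplicative lognormal (0.1 log10 units) for qPCR — and
limit-of-detection censoring (no value is ever emitted strictly between
0 and the LoD).  Default sampling: 0–30 h, 10 points, triplicate.
None of the noise magnitudes are published; all are config-exposed.
What the generator does *not* emulate: sporulation-driven OD decline,
cell lysis, solvent-shift metabolism, headspace partitioning, and
pre-culture adaptation.  Passing recovery tests therefore show the
inference machinery is sound under the stated noise model — not that
real chromatograms behave this gently.

## Numerical choices

LP: HiGHS via scipy; feasibility/optimality tolerances 1e-9 (1e-10 for
the parsimonious stage); reported fluxes below 1e-9 truncated to zero;
"unbounded" reactions capped at ±1000 mmol·gDW⁻¹·h⁻¹ so a genuinely
unbounded LP signals a modelling bug.  Ratio constraints are strict
equalities.  Degenerate inputs: empty cultures return zero derivatives;
a species with zero reference uptake is omitted from yield reports; FVA
retries an infeasible objective pin once with 1e-9 slack.

## Known limitations

- The per-glucose yields are structurally exact in the surrogate
  (linear homogeneity makes them independent of the kinetic
  trajectory), so dynamics validate against data only at the
  yield/ratio level, not pointwise in time.
- The fitted/optimal growth-rate comparison uses the peak specific
  growth rate along the batch; other summaries (time-averaged rate)
  shift the NO3-regime percentage by a point or two.
- No maintenance energy, product inhibition, or death terms; H2
  inhibition of the fermenter enters only through the fitted ratio
  constraints.
- The respirer model is deliberately rigid; its inferred fluxes are
  insensitive to condition changes by construction.
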