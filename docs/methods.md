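# Methods

## The unit farm and its governing equations

The modelled production unit is a small mixed farm with three parts: a
vegetal subunit of area *A*_v growing plant food for people, a forage
subunit of area *A*_f growing served cattle feed (hay, silage, greenchop),
and a confined beef herd whose areal footprint is neglected. The farm's
only nitrogen sources are atmospheric deposition *d* (applied to both
cropped subunits), symbiotic fixation (*f*_v, *f*_f, subunit-specific
because legume shares differ between food rotations and forage stands),
and the herd's manure. Units throughout are kg N, ha, years, and cow-years.

Steady-state N conservation per subunit gives

    y_v = rho_v (d + f_v + gamma * alpha * n_m / A_v)        (vegetal)
    y_f = rho_f (d + f_f + (1-gamma) * alpha * n_m / A_f)    (forage)
    n_m = beta * A_f * y_f                                   (herd)

with retention fractions rho in (0, 1] (the productive share of available
N; the complement leaches), manure partition gamma in [0, 1], alpha the
plant-available manure N per cow-year, and beta the herd demand in
cow-years per kg forage N. The solver enforces conservation exactly: per
subunit, deposition + fixation + manure = yield + leached, and the full
itemized ledger is returned with every solution.

**Default geometry.** *A*_v = 1 ha and *A*_f = 3/7 ha. The 3/7 ratio
conserves the share of cropland used for feed in the present US system.
(Source material for this model states the two areas inconsistently in one
place, swapping which subunit is the 1-ha one; we adopt the convention
consistent with the stated ratio and the system schematic — vegetal 1 ha,
forage ≈ 0.43 ha — and note the other reading here rather than silently
resolving it.)

**gamma = 1 is the default and the optimum.** With all manure applied to
the vegetal subunit the system is triangular (solve forage, then herd,
then vegetal). For gamma < 1 the manure returned to the forage subunit
feeds back on forage yield; substitution gives
n_m = beta·A_f·rho_f·(d+f_f) / (1 − beta·rho_f·(1−gamma)·alpha), finite
only when the loop gain beta·rho_f·(1−gamma)·alpha < 1. A supercritical
gain raises a dedicated error naming the offending product. For constant
retention the human-food yield is non-decreasing in gamma (the sweep
utility demonstrates this; the derivative of the gamma-dependent factor is
proportional to 1 − beta·rho_f·alpha > 0 under subcriticality), which is
why all-manure-to-food is the default.

**The combined single-expression form.** Substituting the gamma = 1
equations into one line yields
y_v = rho_v[(d + f_v) + alpha·beta·rho_f·(A_f/A_v)(d + f_f)]. A printed
variant of this expression omitting rho_v on the (d + f_v) term circulates
in the source material; it is inconsistent with direct substitution and is
not implemented. The package computes the substitution-consistent form and
tests it against the sequential solve to machine precision.

**Retention as a function of N availability.** Besides constant rho, a
saturating family rho(N) = rho_max · K/(K + N) is provided: the retained
fraction falls (leaching grows) as a subunit is loaded. The coupled system
(rho depends on availability, availability depends on the solve) is solved
by damped Picard iteration on the two subunit availabilities: evaluate the
curves, re-solve the constant-rho budget, blend availabilities with
damping 0.5, repeat to relative tolerance 1e-10 with a 1000-iteration cap
(non-convergence raises, reporting the last residual). With constant
curves the first iteration is already exact. The exact functional form
used in the empirical source is not available; the saturating family is a
documented stand-in with the right monotonicity.

## Herd and physiology

Every animal category is a fixed ratio per mother cow (defaults: 4 bulls
and 16 replacement heifers per 100 cows, 0.7 calves per cow-year), so herd
composition, forage demand, manure, and beef output all scale linearly
with n_m. n_m is real-valued; fractions of a cow per 1.43-ha farm are
meaningful once tens of millions of farms are counted.

The diet is forage of one of three named quality classes plus 5% by mass
of energy- and protein-rich agroindustrial byproducts (roughly today's
share). Quality nominals (net energy Mcal/kg DM, N fraction): high
1.32 / 0.025, medium 1.20 / 0.022, low 1.08 / 0.019; byproducts 1.9 /
0.028.

Physiology is a pluggable registry; the shipped `net_energy` default uses
standard beef net-energy logic per "one cow and her associated animals":

- dry-matter intake = energy requirement (default 11,000 Mcal/cow-unit-y)
  ÷ mass-weighted diet energy density;
- N intake = intake × diet N fraction;
- N retained = live-mass output (calves/cow-y × finished live weight,
  default 0.7 × 570 kg) × body N fraction (0.025);
- manure N = N intake − N retained, exactly (the N balance is closed by
  construction, and a diet too dilute to cover retention is rejected);
- alpha = manure N × plant-available fraction (default 0.5, covering
  collection, storage and application losses);
- 1/beta = intake × (1 − byproduct share) × forage N fraction;
- beef output = live-mass output × boneless-edible fraction (0.43, a
  calibration knob, not an asserted measurement).

The detailed empirically calibrated cattle equations used in the source
material are not reproduced here; this default captures their structure
(energy-driven intake, mass-balance excretion) and calibrated coefficient
sets can be registered under other names without code change. Absolute
alpha and beta — and therefore the stochastic headline outputs — depend on
this choice.

## Monte Carlo design

Uncertain parameters are drawn independently from configured distributions
(families: point, uniform, truncated-normal at 0, lognormal; all respect
non-negativity). The default design is 250 realizations × 3 forage
qualities; summaries report the pooled mean ± 1 SD over all 750 members
(the whisker convention used for every headline output) plus per-quality
summaries. Each (quality, realization) pair has its own RNG stream seeded
from (seed, quality index, realization index), so any subset reproduces
bit-identically. Realizations whose solve fails are recorded and excluded
rather than resampled — resampling would bias toward benign parameter
regions — and more than 10% failures aborts the run. The distribution
families and their independence are configuration, not empirical claims;
the source material does not state them.

## Food and nutrient accounting

The vegetal hectare carries 14 crop items at equal 1/14-ha land shares by
default (the contrast "0.43 ha for beef vs ~0.07 ha per plant item").
Each item receives the subunit N yield × its land share; its edible mass
is that N divided by the item's edible-mass N content, capped at
(1 − yield penalty) × its conventional yield × share. The 15% default
penalty is an output ceiling relative to conventional practice (the
alternative reading — penalizing N availability — is not used; the cap
convention makes the penalty bind visibly on low-N, high-mass items).
Surplus N above a cap is tracked but not converted to food. Nutrients
follow linearly from mass via per-kg composition columns; protein is
checked against 6.25 × N content per item (default tolerance 20%,
per-item overrides allowed). Beef contributes through its own composition
row. Per-capita daily deliveries are finally expressed as ratios to a
mean-American-diet availability baseline; zero-baseline nutrients are
flagged, never divided.

## Upscaling and averted inputs

Deployment is deliberately naive: the scenario area (default 1.05 × 10^8
ha) divided by the unit-farm area gives the farm count; national totals
are farm means × count; per-capita values divide by the population
(3.3 × 10^8) and 365. Averted fertilizer and GHG are production-side
counterfactuals: Σ production × per-item conventional intensity, compared
with reference national totals. Because field operations are still
required, only 75–90% of the gross GHG figure is a net saving; both ends
of the band (field-operations share 0.10–0.25) are reported, as are the
averted shares of both total and agricultural reference emissions — the
"~10% of national emissions" statement is reported gross, alongside the
net band, since the two readings cannot be fully separated.

## Scenarios

Three land-use counterfactuals share the nitrogen-input draws (common
seed): the mixed reference; "rewild" (no cattle, forage land out of
production, 1 ha vegetal without manure); and "all-vegetal" (no cattle,
full 1.43 ha vegetal without manure). Rewilded land contributes zero food
and zero N flows. The same 15% yield penalty applies in all three (whether
no-manure systems deserve a different penalty is unresolved; uniform
application is the documented choice). The adults-supported metric is
protein ÷ (75 g/d × 365); the reference bar pools the three
forage-quality ensembles.

## Synthetic data and calibration

All inputs are generated, seeded, and annotated: no measurement is
shipped. Two presets separate concerns. `uncalibrated` uses round nominal
values, constant retention, and point-mass distributions — it exercises
every code path and underpins the degenerate-ensemble tests.
`calibrated` tunes a small, explicitly listed set of values (retention
coefficients, the forage-fixation mean, reference national totals, two
baseline carotene rows) so the default ensemble lands near documented
headline bands: per-farm protein ≈ 132 kg/y (≈ 4.8 adults at 75 g/d),
beef ≈ 74% of the 52 g/d baseline, averted fertilizer ≈ 58%, averted GHG
≈ 10% of the fixture's national total and ≈ 110% of its agricultural
total, carotene ratios ≈ 11× and 9×. Every tuned value is marked "tuned"
with its target in the provenance table; untouched values are marked
"nominal". Micronutrient compositions carry a ±2% seeded jitter so
different seeds give distinct but equally plausible bundles without moving
any calibrated quantity.

What passing tests show — and what they do not: the suite establishes the
model's structural properties (exact conservation, closed-form/sequential
equivalence, gamma-optimality, linearity, determinism) on any inputs, and
band-level reproduction only under the calibrated preset. Real deposition,
fixation, and diet data would shift absolute outputs; the structural
results would not change.

## Numerical choices and degenerate inputs

Relative tolerance 1e-10 and damping 0.5 for the retention fixed point;
zero-area forage is treated as "no herd" (n_m = 0) rather than an error;
zero N inputs yield the zero solution in one iteration; a zero baseline
nutrient is flagged not divided; herd size, yields, and all deliveries are
validated non-negative at construction. Ensemble SDs of bit-identical
members are mean-subtraction round-off (≈1e-16 relative), which is why
degeneracy tests compare SD against each output's scale.

## Problem sizes

Default runs use 250 × 3 ensemble members (a few seconds on one CPU);
examples use 40–60 realizations per quality, which is ample for the
mean ± SD displays they print. The brute-force retention oracle in the
test suite uses a 400 × 400 grid on a single small instance.

## Known limitations

Nitrogen only (no P/K co-limitation); annual steady state (no seasonality
or transition dynamics); one homogeneous farm replicated everywhere (no
spatial heterogeneity, no GIS delimitation — the deployment area is a
scalar input); beef only (no dairy, poultry, pork, or eggs); production-
side aversion accounting rather than consumption-side LCA; exports fixed
at zero; no economics. The calibrated preset's absolute outputs inherit
the stand-in physiology and synthetic tables; treat them as a
demonstration of the method, not as empirical findings.
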