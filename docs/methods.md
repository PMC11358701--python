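# Methods

## Model structure and assumptions

The cohort model has four states — PFS (on first-line therapy), PFS-2 (on
second-line therapy after first progression), PD (progressed past second
line), Death — on 21-day cycles. A 20-year horizon is 348 cycles
(`round(20 × 365.25 / 21)`). State membership is valued at cycle start; no
half-cycle correction is applied. Death is absorbing; deaths from PFS and
PFS-2 occur only at the background (natural) rate, so all excess disease
mortality is routed through PD. Transition probabilities are time-dependent,
rebuilt each cycle from the three survival functions (see README for the
equations). Probabilities falling outside [0, 1] are clipped and the row is
re-normalized through its diagonal, so every row stays stochastic even under
degenerate inputs; a non-positive PD→Death denominator (S ≤ P2) zeroes that
transition rather than crashing.

**The two printed denominator forms.** The PD→Death probability divides the
OS drop by either S(t) − P2(t+1) ("lead", the default here) or
S(t) − P2(t) ("lag"); both appear in the health-economics literature and
both are implemented (`pd_denominator`). The lag form is the
occupancy-consistent one: at cycle start the PD state holds S(t) − P2(t) of
the cohort, so dividing the cohort-scale death flow by that quantity makes
cumulative trace deaths track 1 − S(t). The consistency test in the suite
therefore exercises the lag form; with 21-day cycles the two differ by at
most a couple of percent of occupancy.

**Consistency limits.** The PFS-2→PD probability divides the P2 drop by
P2(t), while the state only holds P2(t) − P(t); the trace therefore tracks
the generating curves exactly only where PFS has largely emptied before
second progressions accumulate. This is a property of the model family
itself, not of the implementation; the trace-consistency test constructs a
regime (fast-emptying PFS, well-separated P2 and S) where the premise
holds. Independently fitted curves can also cross in the extrapolated tail,
which would freeze the PD state (denominator ≤ 0 forever); the pipeline
prevents this by capping the curves pointwise to P ≤ P2 ≤ S after
selection, a standard curve-consistency adjustment. Where capping makes
P2 = S, the PD→Death probability becomes 1 under the lead form, correctly
draining a state that should be empty.

**Background mortality** defaults to a constant annual death probability of
0.0197 (a general-population all-cause figure for a 65-year-old-plus
cohort), converted per cycle as 1 − (1 − p)^(21/365.25). An age-indexed
life table can be supplied instead (ages beyond the table carry the last
row forward); no external download is performed.

## Pseudo-IPD reconstruction

Digitized coordinates (time, survival) plus a numbers-at-risk table are
inverted to per-patient records with the standard interval-wise algorithm:
risk-table intervals bound the reconstruction; coordinates inside an
interval are treated as exact event locations; the censoring count per
interval is found by iterating until the implied end-of-interval risk count
matches the table, with censor times spread uniformly over the interval;
fractional event counts are resolved by largest-remainder apportionment so
interval totals are exact. The reconstructed record count always equals the
initial number at risk; implied negative censoring (an inconsistent table)
is clamped to zero and logged. Optional calibration to a reported event
total (`calibrate_events`) relabels latest-time records and is off by
default. Round-trip fidelity on jitter-free synthetic curves is sup-norm
< 0.02 across all seven families at n = 300 (exactly zero when there is no
censoring, since every event time is then a coordinate).

## Parametric fitting and selection

Right-censored log-likelihood `Σ_events ln f(t) + Σ_censored ln S(t)`,
maximised by Nelder–Mead followed by an L-BFGS-B polish from a fixed list of
moment-style starting values per family (reproducible multi-start).
Standard errors come from a central-difference Hessian in natural parameter
space. Parameterizations:

| family        | parameters            | notes                                   |
|---------------|-----------------------|-----------------------------------------|
| exponential   | rate λ                | S = exp(−λt)                            |
| weibull       | shape k, scale λ      | scipy `weibull_min`                     |
| loglogistic   | shape c, scale s      | scipy `fisk`                            |
| lognormal     | mu, sigma             | mu on the log-time scale                |
| gamma         | shape a, scale s      |                                         |
| gengamma      | a, c, scale           | scipy `gengamma` (a, c > 0); nests gamma (c=1) and Weibull (a=1) |
| gompertz      | shape b ∈ R, rate λ   | hazard λe^{bt}; b < 0 gives a plateau exp(λ/b) |

Selection takes the lowest-AIC converged fit that passes two plausibility
filters, with ties broken by BIC then parameter count: (i) the candidate
must not cross above its companion curve (PFS under PFS-2, PFS-2 under OS)
anywhere on the horizon grid, within a crossing tolerance; (ii) its
extrapolated survival at the horizon must sit below a ceiling. The
function-level ceiling default is 0.40; the shipped base configuration uses
0.10 because 20-year survival in advanced EGFR-mutant NSCLC is below that,
and a crossing tolerance of 0.06, sized to the sampling noise between
independently estimated endpoint curves at trial-size cohorts (a genuinely
implausible fit, e.g. PFS plateauing above OS, violates by far more). By
default one family is selected per endpoint jointly across arms (lowest
summed AIC passing the filters in every arm), reducing
distribution-dependence of the comparison; per-arm selection is a switch.

The comparator arm's OS uses the proportional-hazards transform
S^HR with a constant HR (time-varying hazard ratios are out of scope). In
`direct` OS mode both arms' OS curves are fitted from data instead.

## Valuation

Dosing for a reference 65-year-old (70 kg, BSA 1.86 m², creatinine
clearance 70 mL/min): osimertinib 80 mg/day; pemetrexed 500 mg/m² every
cycle; platinum during the four induction cycles only (carboplatin at
AUC 5 by Calvert, dose = AUC × (Ccr + 25), or cisplatin 75 mg/m²). Unit
prices are 2023 US$ per mg; no vial rounding or wastage is applied.

* **Discontinuation.** Cumulative discontinuation proportions (e.g.
  pemetrexed 0.7536 in the combination arm) scale that agent's per-cycle
  cost by (1 − rate) across the PFS state — an expected-cost reading, since
  no time-to-discontinuation curve is published. Administration fees are
  not scaled.
* **Infusion fees.** CPT-style hour structure: first hour $132.16, each
  additional hour $28.47. Pemetrexed occupies the first hour and the
  platinum agent one additional hour (induction 2 h, maintenance 1 h);
  second-line regimens bill 1–3 h analogously. Hour assignments are config.
* **Second-line basket (PFS-2).** A market-share basket, equal shares by
  assumption: platinum–pemetrexed; a first-generation TKI (half gefitinib
  250 mg/day, half afatinib 40 mg/day); a bevacizumab-containing triplet
  (bevacizumab 15 mg/kg + carboplatin AUC 5 + nab-paclitaxel 260 mg/m²);
  pembrolizumab 200 mg flat. Basket cost applies to the fraction of PFS-2
  occupants still on treatment: new progressors enter on treatment and the
  on-treatment fraction decays by the per-cycle discontinuation probability
  (0.03) on top of state transitions — an explicit auxiliary occupancy,
  since a cohort trace has no per-patient clock.
* **Other components.** Follow-up $542.65/month and imaging $114.54 per
  3 months are converted to cycle shares via 21/30.4375 and 21/91.3125.
  PD accrues best supportive care $3,006.28/cycle. One-time at entry: EGFR
  testing $1,199.53 and expected SAE management cost Σ risk × cost, with a
  matching one-time QALY decrement Σ risk × disutility × one cycle length
  (SAE disutilities are assumed to last one cycle). End-of-life care
  $40,708.33 is billed once per incident death at the death cycle.
* **SAE arm labels.** The sourced risk table lists the higher haematologic
  SAE risks under monotherapy, which contradicts the clinical expectation
  for a chemotherapy-containing arm; both vectors are carried verbatim and
  `sae_risks.swap_arms` exchanges them without asserting intent.

Costs and QALYs are discounted by (1 + r)^(−t·21/365.25) with r = 0.03
(range 0–0.08). Totals are also reported at a 10-year horizon alongside the
20-year totals.

## Sensitivity analyses

One-way bounds: costs, BSA, Ccr and weight ±25%; proportions and utilities
±10% capped at 1; discount 0 to 0.08; the OS HR over its CI (0.57–0.97).
Tornado entries report the ICER at each bound and are sorted by spread;
model failures flag the entry rather than dropping it.

PSA hyperparameterization (the exact published scheme being unstated, this
is the package's documented method-of-moments rule): gamma with SD = 10% of
the mean (shape 100, scale mean/100); beta by moment matching of (m, 0.1m),
falling back to a ±10% uniform when the moments are infeasible (m near 0 or
1); normal (mean, 0.1·mean) for BSA/Ccr/weight; uniform(0, 0.08) for
discount; lognormal for the HR with log-SD = (ln 0.97 − ln 0.57)/3.92.
Draws are mutually independent; survival-fit coefficient uncertainty is
deliberately outside the PSA (only tabled parameters are sampled), a known
limitation. 1000 replicates are the reference size; the acceptance script
uses 200 and the end-to-end test 100, which bounds the CEAC's Monte-Carlo
error at a few percentage points. Setting the SD fraction to zero collapses
every distribution to its baseline and reproduces the base case exactly.

The DSA/PSA model closure holds the fitted survival coefficients at their
base-case estimates and re-evaluates everything downstream; only an HR
override triggers a re-trace (of the combination arm), so a full 348-cycle
re-evaluation costs milliseconds.

## Synthetic data generator

Event times are drawn from a chosen family per arm/endpoint, censored by an
independent exponential process and an administrative cutoff, and rendered
as product-limit step coordinates plus exact numbers-at-risk — emulating
what one obtains by digitizing a published figure. Digitization jitter is
additive Gaussian noise on the probability scale, truncated to [0, 1] and
projected back onto non-increasing sequences (pool-adjacent-violators).

The shipped preset mimics the motivating trial's shape: 279
patients/arm, Weibull PFS with medians 29.4 (combo) vs 19.9 (mono) months,
second-PFS medians 36 vs 30 months, mono OS median 38.6 months, combo OS
exactly S^0.75 (for Weibull, a scale shift by 0.75^(−1/shape)), light
random censoring (0.005/month) and administrative cutoffs of 45 months
(PFS, PFS-2) and 62 months (OS); risk tables every 3 months. Subgroup
presets vary only the PFS medians. What it does **not** emulate: within-
patient correlation between endpoints (curves are drawn independently, so
small sampling crossings occur — handled by the selection tolerance and
capping), digitization pixel error structure, informative censoring, cure
fractions, and delayed treatment effects. Passing tests on this preset
therefore demonstrate pipeline correctness on trial-shaped data, not
agreement with any particular trial's patient-level reality.

## Numerical choices

Cycle length constants: 21/30.4375 months, 21/365.25 years. Optimiser
tolerances: Nelder–Mead xatol 1e-8/fatol 1e-10, maxiter 2000. Likelihood
guards: times clipped to ≥ 1e-8, survival probabilities floored at 1e-300
inside logs, non-finite likelihoods mapped to a large penalty; a fit is
flagged non-converged (and excluded from selection) only if every start
fails. Trace mass conservation holds to 1e-12 per cycle by construction.
Ties in selection: AIC, then BIC, then fewer parameters.

## Known limitations

Second-line market shares, infusion hour assignments and the SAE disutility
duration are assumptions exposed in the config. The PFS-2→PD equation's
denominator makes the trace only approximately consistent with the fitted
curves when PFS and PFS-2 overlap heavily (see above). No correlation
structure in the PSA; no EVPI; no societal costs; no tunnel states or
microsimulation.
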