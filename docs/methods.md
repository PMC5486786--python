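# Methods

## Model structure

The package implements a cost-consequence analysis (CCA): costs and an array
of health outcomes are reported side by side, never collapsed into a single
cost-effectiveness ratio. The underlying structure is a deterministic
decision tree evaluated on a cohort of `cohort_size` patients per arm
(default 1000) over a `horizon_weeks` horizon (default 104 weeks / 2 years),
without discounting — at a 2-year horizon discounting would be cosmetic and
is deliberately omitted.

Branches are **marginal tallies**. Each outcome (response, remission,
discontinuation, safety event) has its own input probability, and its
expected count is `round-half-up(p · n)`, independent of the other branches.
We do not construct a joint patient-level state in deterministic mode: the
published evidence for this comparison consists of marginal rates per
subgroup and arm, and any joint structure would be invented. The stochastic
mode replaces each tally with a `Binomial(n, p)` draw (one seeded generator,
branches drawn in a fixed order); it quantifies sampling noise around the
marginal tallies, not patient-level correlation. Serious adverse events and
local injection-site reactions are treated as mutually exclusive event
classes and tallied on separate branches. Discontinuation is an outcome
measure, not a cost modifier: by default, discontinuing patients accrue
full-horizon drug cost (intention-to-treat accounting). The
`prorate_discontinuation` flag implements the alternative reading — the
discontinuing fraction accrues half the horizon, i.e. uniform stopping
times — for users who want discontinuation to act on costs.

## Subgroups

ACPA serostatus: negative below 25 AU/mL, positive at or above. Positive
patients split into four empirical titre quartiles (Q1 28–235, Q2 236–609,
Q3 613–1046, Q4 1060–4894 AU/mL). The printed quartile bounds leave small
gaps (25–27, 610–612, 1047–1059, above 4894); because synthetic cohorts can
generate any titre, the assignment function is made total by mapping gap
titres to the nearest quartile interval, ties to the lower quartile. This
convention is ours; it affects only synthetically generated titres, never
the bundled subgroup-level inputs.

Clinical inputs are bundled for the negative, positive, Q1 and Q4 subgroups
(the printed evidence covers exactly those). Runs for Q2/Q3 on the bundled
fixture raise a lookup error; user decks may supply them.

## Cost engine

Per arm, four payer components plus an optional societal component:

* **Drug acquisition** — `floor(horizon/interval)` administrations, each
  consuming `ceil(dose_mg / unit_size_mg)` whole priced units (single-use
  syringes: wastage is paid for). Weight-based dosing multiplies the dose by
  `weight_kg` (default 80.5 kg, the trial cohort's mean weight, the only
  weight used for costing).
* **Concomitant medication** — mg/day × days × per-mg price × exposed
  fraction, per regimen drug. Per-mg prices are computed from pack price and
  pack size at full precision; printed per-mg columns are display values
  (half-up, 2 decimals) only.
* **Monitoring** — outpatient visits, radiographic exams and blood-test
  series at per-year rates × years × unit costs; one schedule for both arms
  (per-arm schedules can be configured by building two models).
* **AE management** — one per-episode tariff per counted patient. Named
  frequent AEs use their own tariff when listed; any AE type outside the
  named list is priced at the mean of the listed frequent-AE tariffs
  ("other AEs" aggregation). Serious events, malignancies and autoimmune
  disorders carry hospitalization-scale tariffs.

Money is computed in floats and snapped to currency minor units (cents,
half-up) when a breakdown is assembled; the total is the exact sum of the
component cents, so additivity holds to the cent by construction. Display
rounding never feeds back into arithmetic.

## Incremental results

For each outcome: ΔE = responder count difference (abatacept − adalimumab),
ΔC = total cohort cost difference. Two monthly normalizations are always
reported, because the normalization of the published per-outcome figure is
not recoverable: `(ΔC/ΔE)/months` (cost per extra responder per month,
undefined/flagged at ΔE = 0) and `ΔC/(n·months)` (per member per month,
always defined). The `favours` label applies strict dominance: an arm is
favoured iff it is cheaper with at least equal health, or equally priced
with more health; trade-off quadrants and exact ties are `indeterminate`.
We deliberately do not rank trade-off cells — that value judgment is the
decision-maker's, which is the point of a CCA.

## One-way sensitivity analysis

Eligible parameters: biologic unit prices, monitoring rates and unit costs,
AE tariffs, and all safety incidences for the analysed subgroup. Fixed by
rule (not subject to parameter uncertainty): time horizon, dose schedules,
concomitant drug prices, cohort size, patient weight; parameters with mean
zero never vary.

Distribution assignment: a supplied 95% CI is used directly; otherwise
proportions get `Beta` with SD = mean, and continuous parameters get a
symmetric triangular with SD = 0.3 × mean. "Varied on the 95% CI" is
operationalized as evaluation at the 2.5th/97.5th percentiles — two
deterministic model evaluations per parameter, which is what a tornado bar
is. Numerical notes:

* Beta shapes by method of moments: `α+β = m(1−m)/s² − 1`, `α = m(α+β)`.
  The SD = mean rule is infeasible for means ≥ 0.5 (it would require
  `α+β ≤ 0`); such parameters have their SD clamped to 95% of the maximum
  feasible SD `√(m(1−m))`, with a warning. The clamp preserves the rule's
  intent (very wide uncertainty) without crashing.
* Symmetric triangular half-width is `s·√6`. If the support would cross
  zero for a nonnegative-by-nature parameter, the half-width is clamped to
  the mean (support `[0, 2m]`, mode `m`): mean-preserving, SD shrunk. The
  renormalization is our choice among several mean-preserving truncations;
  it keeps the distribution symmetric and the mode at the mean.
* Tornado entries are sorted by descending result range, ties broken
  lexicographically by parameter id, so output order is deterministic. A
  model failure at a bound flags the entry and the scan continues.

On the bundled decks the biologic acquisition prices dominate the tornado in
Germany, Spain, the US and Canada, and pushing the abatacept price to its
upper bound flips the incremental cost from negative (cost saving) to
positive — both directions the analysis is expected to show.

## Societal perspective (Germany and Italy)

Indirect costs enter through a schedule of annual societal cost per HAQ-DI
band (bands partition [0, 3]; costs nondecreasing with severity, as the
human-capital approach implies). The cohort is allocated to bands by two
conditional mixes — HAQ-DI responders concentrated in milder bands,
non-responders in worse ones — because only response rates exist at the
subgroup level. Allocations are expected (fractional) counts and always sum
to n. The societal component is a separate breakdown entry, so
`societal total = payer total + societal component` per arm, and an all-zero
schedule reproduces the payer run exactly.

The Italian construction (work absence plus early-retirement pensions) is
provided as `italian_indirect_per_patient`: employed fraction × days lost ×
daily income, plus pensioner fraction × mean annual pension cost. It
anchors user-supplied schedules; the bundled schedules do not re-derive it.

## Synthetic inputs: what they emulate and what they do not

The generators stand in for trial-level inputs that exist only in an
unpublished study report:

* **Safety incidences** (`default_safety_fixture`): the ten per-1000-patient
  event-count pairs that *were* published are read back as incidences
  (count/1000 — exact, because the model cohort is exactly 1000). All other
  classes (named frequent AEs, malignancy, autoimmune, discontinuations,
  and all of Q2/Q3) carry package defaults chosen to mirror the qualitative
  arm asymmetry (more injection-site reactions and safety discontinuations
  on adalimumab). `generate_safety_inputs` draws scenario variants from
  beta priors (concentration 400) centred on the fixture: `paper_like`
  additionally enforces strictly more LISRs on adalimumab in every
  subgroup; `null` makes the arms identical, so safety-driven incremental
  AE costs are exactly zero downstream.
* **Patient baselines**: age ~ Normal(51, 13) clipped to [18, 90], 79%
  female, HAQ-DI = 3·Beta(2, 4), weight ~ Normal(80.5, 15) clipped
  symmetrically (mean preserved), titres 23.6% negative and the rest
  log-uniform within a uniformly chosen quartile interval. These
  distributions are package conventions — documented as such, not sourced
  values — sufficient to exercise subgroup assignment and weight-based
  dosing.
* **Resource use**: 4 outpatient visits, 1 radiograph, 4 blood-test series
  per patient-year, and a concomitant regimen (methotrexate 20 mg/week for
  all; prednisone 5 mg/day for half; hydroxychloroquine/sulfasalazine for
  10% each; NSAIDs 1200 mg/day for 30%). Defaults reflect routine
  rheumatology follow-up; drugs absent from a country's printed price block
  are omitted for that country rather than imputed.
* **AE tariffs and HAQ-band schedules** are synthetic (clearly labelled in
  the data module): GP-visit/day-case scale for frequent AEs and LISRs,
  hospitalization (DRG) scale for serious events, and rising annual
  societal costs per HAQ band, with a per-country price-level factor.

Consequently, passing tests demonstrate that the *mechanism* is faithful —
printed rates and counts reproduce exactly, signs and rankings match the
published narrative, conservation/symmetry laws hold — but cohort-level
currency totals depend on the synthetic tariffs and schedules and are *not*
estimates of the published country totals. That is a property of the public
evidence, not of the implementation.

## Numerical choices and degenerate inputs

* Expected counts round half-up (counts are reported as integers).
* Zero horizon: all time-driven components are zero; AE management is
  per-episode and horizon-independent.
* Zero-gain cells: flagged indeterminate ratio; zero incremental cost gives
  a zero ratio regardless of gain sign.
* Determinism: every stochastic operation takes an explicit seed via
  `SyntheticScenario` or function argument; a single `numpy` generator per
  operation, iteration in sorted key order. The default CLI seed is a fixed
  constant, never the clock.
* Problem sizes in the shipped checks: cohorts of 1000 (the model's own
  size), 500 replicate draws for sampling-mean checks, 10⁵ draws for
  distribution-moment checks — small enough to run in seconds, large enough
  that the tolerance arguments (standard-error bounds, stated in the tests)
  are meaningful.

## Known limitations

* Deterministic branch tallies carry no patient-level correlation between
  outcomes; the stochastic mode treats branches as independent binomials.
* The 2-year horizon is the evidence horizon; no extrapolation, treatment
  sequencing or lifetime HAQ progression is modelled. (The HAQ-band
  mechanism operates strictly within the horizon.)
* Currency conversion and CPI inflation are out of scope; prices are used
  as printed per country, with any inflation adjustment left to a
  user-supplied multiplier on the deck values.
* Societal runs are implemented for Germany and Italy only, and their
  absolute magnitudes inherit the synthetic schedules' scale.
* Cell-level published per-outcome monthly cost values are not reproducible
  from public data (they depend on unpublished tariffs); the package's
  acceptance surface is therefore exact reproduction of printed rates,
  counts and prices plus the qualitative sign/ranking structure.
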