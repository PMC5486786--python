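# rheumcca

Cost-consequence analysis (CCA) of subcutaneous **abatacept** (125 mg weekly)
versus **adalimumab** (40 mg bi-weekly), both on background methotrexate, in
rheumatoid arthritis — stratified by serum **ACPA** (anti-citrullinated
protein antibody) status, for Germany, Italy, Spain, the US and Canada.

It is written for health economists and HTA analysts who want a transparent,
scriptable replacement for the spreadsheet decision models this kind of
analysis usually lives in: every input is a diffable CSV table, every run is
seed-reproducible, and every stage (cohort tallies, cost components,
incremental results, sensitivity analysis) is an importable function.

## The model

A deterministic decision-tree cohort model simulates *n* = 1000 patients per
arm over a 2-year horizon (no discounting). For each ACPA subgroup *g*
(negative: titre < 25 AU/mL; positive: ≥ 25 AU/mL; positive quartiles
Q1–Q4) and arm *t*:

* **Health outcomes.** Each branch is a marginal tally: the expected count of
  patients achieving outcome *k* is `round(p_gtk · n)`, where `p_gtk` is the
  observed response/remission proportion (ACR20/50/70/90, HAQ-DI improvement
  ≥ 0.3, DAS28-CRP < 2.6, CDAI ≤ 2.8, SDAI ≤ 3.3). Safety branches
  (SAEs, injection-site reactions, malignancies, autoimmune disorders,
  discontinuations) are tallied the same way from 2-year incidences. A
  stochastic mode replaces each tally with a Binomial(n, p) draw.
* **Costs.** Per arm: drug acquisition (whole single-use syringes per
  administration, 104-week horizon), concomitant medication (mg/day ×
  per-mg price × exposed fraction), disease monitoring (visits, radiographs,
  blood tests), and AE management (per-episode tariffs; hospitalization for
  serious events). Totals are carried in currency minor units so components
  always sum exactly.
* **Incremental results.** For each outcome, the incremental cohort cost
  ΔC = C_aba − C_ada and incremental gain ΔE (responder counts) yield the
  monthly cost per extra responder (ΔC/ΔE)/24 and the per-member-per-month
  value ΔC/(n·24). Dominance cells (cheaper and at least as effective) are
  labelled; trade-off cells are flagged rather than silently ratioed.
* **OWSA.** One-way sensitivity analysis varies each eligible parameter
  between the 2.5th/97.5th percentiles of its assigned distribution —
  supplied 95% CI if available, else beta with SD = mean for proportions,
  else triangular with SD = 30% of mean — and ranks parameters by the range
  of the incremental cost (tornado).
* **Societal extension (DE/IT).** Annual indirect costs per HAQ-DI
  disability band, allocated by responder/non-responder band mixes, added as
  a separate cost component.

Inputs the original trial's study report never published as rates (safety
incidences, resource-use frequencies, AE tariffs, HAQ-band cost schedules)
are supplied by a first-class synthetic-input module with documented
defaults; safety defaults are recovered from the published per-1000-patient
event counts.

## Worked example

```python
from rheumcca import CostConsequenceModel, Subgroup

model = CostConsequenceModel.from_fixtures("DE", Subgroup.Q4)
print(model.fit().summary())
```

```
Cost-consequence analysis: abatacept vs adalimumab
================================================================
Country: DE (EUR, price year 2016)   Subgroup: Q4
Cohort: 1000 per arm   Horizon: 104 weeks   Perspective: payer   Mode: deterministic

Cohort costs by component
----------------------------------------------------------------
       arm currency  drug_acquisition  concomitant  monitoring  ae_management         total
 abatacept      EUR     36,000,640.00 1,313,416.00  585,320.00     152,620.00 38,051,996.00
adalimumab      EUR     45,338,280.00 1,313,416.00  585,320.00     168,080.00 47,405,096.00

Total incremental cost (abatacept - adalimumab): -9,353,100.00 EUR

Incremental cost per health gain (per month of horizon)
----------------------------------------------------------------
subgroup         measure  incremental_gain  incremental_cost  cost_per_gain_pmpm  per_member_pmpm   favours  ...
      Q4           ACR20                97     -9,353,100.00           -4,017.65          -389.71 abatacept
      Q4           ACR90                56     -9,353,100.00           -6,959.15          -389.71 abatacept
      ...
```

Reading: in the highest ACPA quartile, abatacept produces 97 extra ACR20
responders per 1000 patients while saving €9.35M over two years — about
€4,018 saved per extra responder per month, or €390 saved per member per
month — so abatacept dominates on all eight outcomes in this subgroup.
In ACPA-negative patients the ACR70 gain is negative (a flagged trade-off),
matching the weaker case for abatacept at low ACPA titres.

The same analyses are available from the shell:

```sh
rheumcca run --country DE --subgroup q4 --out out/        # CCA + manifest
rheumcca owsa --country ES --subgroup pos --top 10        # tornado table
rheumcca societal --country IT --subgroup q4 --out soc/   # societal view
rheumcca synth --country US --seed 7 --out deck/          # synthetic deck
```

## Layout

| Module | Role |
|---|---|
| `rheumcca.inputs_io` | domain types, deck CSV I/O, bundled printed fixtures |
| `rheumcca.synthetic_inputs` | generators for unpublished inputs (safety, baselines, resource use, HAQ-band schedules) |
| `rheumcca.cohort_engine` | decision-tree tallies, deterministic and binomial |
| `rheumcca.cost_engine` | per-arm cost components and breakdowns |
| `rheumcca.cca` | incremental cost per health gain, favours taxonomy |
| `rheumcca.owsa` | distribution assignment, moment matching, tornado |
| `rheumcca.societal` | HAQ-band indirect costs for Germany and Italy |
| `rheumcca.model` | `CostConsequenceModel` / `CCAResults` / `TornadoResults` |
| `rheumcca.cli_reporting` | `rheumcca` command line, reports, run manifests |

See `docs/methods.md` for the modelling assumptions, parameter defaults and
known limitations.
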