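"""Per-arm cost engine over the model horizon (default 104 weeks, no discounting).

Components:

* drug acquisition — administrations in the horizon times whole priced units
  per administration (single-use syringes: partial units are wasted, so units
  are ceiled) times unit price; weight-based drugs scale the dose by the mean
  patient weight (default 80.5 kg);
* concomitant medication — milligrams per day times days in horizon times the
  full-precision per-mg price times the exposed cohort fraction;
* disease monitoring — outpatient visits, radiographic exams and blood-test
  series at their per-year frequencies times years in horizon;
* adverse-event management — one per-episode tariff per counted patient;
  frequent AEs outside the named tariff list are priced at the average named
  frequent-AE tariff ("other AEs" aggregation).

Per-patient component values are computed at full float precision and snapped
to currency minor units (cents) when the :class:`CostBreakdown` is assembled,
so the total always equals the component sum exactly to the cent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Mapping, Optional

from ._util import to_cents
from .cohort_engine import CohortOutcome
from .exceptions import (
    ComparabilityError,
    DomainError,
    MissingPriceError,
)
from .inputs_io import (
    CountryCostTable,
    DoseSchedule,
    DrugCost,
    ResourceUseSchedule,
    Subgroup,
)

DAYS_PER_WEEK = 7.0
WEEKS_PER_YEAR = 52.0

COMPONENTS = ("drug_acquisition", "concomitant", "monitoring", "ae_management", "societal")


@dataclass(frozen=True)
class CostBreakdown:
    """Cohort-level cost components for one arm, in currency minor units."""

    arm: str
    subgroup: Subgroup
    currency: str
    n: int
    component_cents: Mapping[str, int]

    def __post_init__(self):
        for comp, cents in self.component_cents.items():
            if cents < 0:
                raise DomainError(f"component {comp} must be >= 0, got {cents / 100}")

    @classmethod
    def from_components(
        cls, arm: str, subgroup: Subgroup, currency: str, n: int,
        components: Mapping[str, float],
    ) -> "CostBreakdown":
        return cls(
            arm=arm,
            subgroup=subgroup,
            currency=currency,
            n=n,
            component_cents={k: to_cents(v) for k, v in components.items()},
        )

    @property
    def components(self) -> Dict[str, float]:
        return {k: v / 100.0 for k, v in self.component_cents.items()}

    @property
    def total_cents(self) -> int:
        return sum(self.component_cents.values())

    @property
    def total(self) -> float:
        return self.total_cents / 100.0

    def per_patient(self) -> Dict[str, float]:
        return {k: v / 100.0 / self.n for k, v in self.component_cents.items()}


def doses_in_horizon(schedule: DoseSchedule, horizon_weeks: float) -> int:
    """Number of administrations within the horizon: floor(weeks / interval)."""
    if horizon_weeks < 0:
        raise DomainError(f"horizon_weeks must be >= 0, got {horizon_weeks}")
    return int(math.floor(horizon_weeks / schedule.interval_weeks + 1e-9))


def drug_acquisition_cost(
    drug: DrugCost, horizon_weeks: float, weight_kg: float = 80.5
) -> float:
    """Per-patient acquisition cost of a scheduled (study) drug over the horizon.

    Whole priced units are consumed per administration (ceiling — single-use
    presentation, wastage included).
    """
    if weight_kg <= 0:
        raise DomainError(f"weight_kg must be > 0, got {weight_kg}")
    if drug.schedule is None:
        raise DomainError(f"drug {drug.name!r} has no dose schedule")
    mg = drug.schedule.dose_mg * (weight_kg if drug.schedule.per_kg else 1.0)
    units = math.ceil(mg / drug.unit_size_mg - 1e-9)
    return doses_in_horizon(drug.schedule, horizon_weeks) * units * drug.unit_price


def concomitant_cost(
    regimen: ResourceUseSchedule, costs: CountryCostTable, horizon_weeks: float
) -> float:
    """Per-patient concomitant medication cost: sum over regimen drugs of
    mg/day x days x per-mg price x exposed fraction."""
    if horizon_weeks < 0:
        raise DomainError(f"horizon_weeks must be >= 0, got {horizon_weeks}")
    days = horizon_weeks * DAYS_PER_WEEK
    total = 0.0
    for name, mg_per_day, exposure in regimen.concomitant_regimen:
        drug = costs.drug(name)  # raises MissingPriceError naming the drug
        total += mg_per_day * days * drug.price_per_mg * exposure
    return total


def monitoring_cost(
    use: ResourceUseSchedule, costs: CountryCostTable, horizon_weeks: float
) -> float:
    """Per-patient disease-monitoring cost: per-year rates x years x unit costs."""
    if horizon_weeks < 0:
        raise DomainError(f"horizon_weeks must be >= 0, got {horizon_weeks}")
    years = horizon_weeks / WEEKS_PER_YEAR
    mc = costs.monitoring_unit_costs
    return years * (
        use.outpatient_visits_per_year * mc["outpatient_visit"]
        + use.radiographs_per_year * mc["radiographic_exam"]
        + use.blood_test_series_per_year * mc["blood_test_series"]
    )


def ae_management_cost(outcome: CohortOutcome, costs: CountryCostTable) -> float:
    """Cohort-level AE-management cost: one per-episode tariff per counted patient.

    Named frequent AEs use their own tariff when listed; unlisted AE types are
    priced at the average of the listed frequent-AE tariffs ("other AEs").
    SAEs, malignancies and autoimmune disorders carry hospitalization-scale
    tariffs; LISRs a GP-visit/day-case tariff.  Discontinuations are outcomes,
    not cost events, and are not priced here.
    """
    total = 0.0
    for event, count in outcome.safety_events.items():
        if count == 0:
            continue
        if event in costs.ae_class_costs:
            price = costs.ae_class_costs[event]
        elif event in costs.frequent_ae_costs:
            price = costs.frequent_ae_costs[event]
        elif event == "other_AE" or costs.frequent_ae_costs:
            price = costs.other_ae_cost()
        else:
            raise MissingPriceError(
                f"no management tariff for event class {event!r} in {costs.country}"
            )
        total += count * price
    return total


def arm_total_cost(
    outcome: CohortOutcome,
    costs: CountryCostTable,
    use: ResourceUseSchedule,
    horizon_weeks: float = 104.0,
    weight_kg: float = 80.5,
    *,
    prorate_discontinuation: bool = False,
    societal_component: Optional[float] = None,
) -> CostBreakdown:
    """Assemble the cohort-level :class:`CostBreakdown` for one arm.

    Study-drug and concomitant costs accrue for the full horizon regardless of
    discontinuation by default (discontinuation is an outcome measure, not a
    cost lever); with ``prorate_discontinuation`` the discontinuing fraction
    accrues half the horizon (uniform stopping times).
    ``societal_component`` (cohort-level, optional) adds the societal
    perspective's indirect costs as a separate component.
    """
    drug = costs.drug(outcome.arm)
    per_patient_drug = drug_acquisition_cost(drug, horizon_weeks, weight_kg)
    per_patient_conc = concomitant_cost(use, costs, horizon_weeks)
    if prorate_discontinuation:
        disc_rate = outcome.discontinuations.get("discontinuation_any", 0) / outcome.n
        accrual = 1.0 - disc_rate / 2.0
        per_patient_drug *= accrual
        per_patient_conc *= accrual
    components = {
        "drug_acquisition": per_patient_drug * outcome.n,
        "concomitant": per_patient_conc * outcome.n,
        "monitoring": monitoring_cost(use, costs, horizon_weeks) * outcome.n,
        "ae_management": ae_management_cost(outcome, costs),
    }
    if societal_component is not None:
        if societal_component < 0:
            raise DomainError("societal component must be >= 0")
        components["societal"] = societal_component
    return CostBreakdown.from_components(
        arm=outcome.arm,
        subgroup=outcome.subgroup,
        currency=costs.currency,
        n=outcome.n,
        components=components,
    )


__all__ = [
    "COMPONENTS",
    "CostBreakdown",
    "doses_in_horizon",
    "drug_acquisition_cost",
    "concomitant_cost",
    "monitoring_cost",
    "ae_management_cost",
    "arm_total_cost",
]
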