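"""Societal-perspective extension (Germany and Italy).

Indirect (non-medical) costs are attached through a schedule of annual
societal cost per HAQ-DI disability band: worse functional capacity means
higher productivity loss under the human-capital approach, so band costs are
nondecreasing with band severity.  The cohort is allocated to bands through
two conditional mixes — one for HAQ-DI responders (improvement >= 0.3 units,
concentrated in milder bands) and one for non-responders — because only
response rates, not patient-level HAQ trajectories, are available.

The published schedules themselves (German claims data; Italian absence and
early-retirement pensions) were never printed; the bundled defaults in
:func:`rheumcca.synthetic_inputs.generate_haq_cost_schedule` are synthetic.
:func:`italian_indirect_per_patient` reproduces the Italian construction:
work-days lost times daily income for the employed fraction, plus mean annual
pension cost for the pensioner fraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .cca import CCAOutput, full_cca
from .cohort_engine import CohortOutcome
from .exceptions import DomainError, UnsupportedCountryError, ValidationError
from .inputs_io import (
    ClinicalInputTable,
    CountryCostTable,
    ResourceUseSchedule,
    SafetyInputTable,
    Subgroup,
)

SOCIETAL_COUNTRIES = ("DE", "IT")


@dataclass(frozen=True)
class HAQBandCostSchedule:
    """Annual societal cost per HAQ-DI band; bands partition [0, 3]."""

    country: str
    bands: Sequence[Tuple[float, float, float]]  # (low, high, annual_cost)

    def __post_init__(self):
        if not self.bands:
            raise ValidationError("schedule must have at least one band")
        lows = [b[0] for b in self.bands]
        highs = [b[1] for b in self.bands]
        costs = [b[2] for b in self.bands]
        if not math.isclose(lows[0], 0.0) or not math.isclose(highs[-1], 3.0):
            raise ValidationError("bands must cover [0, 3]")
        for (hi, lo_next) in zip(highs, lows[1:]):
            if not math.isclose(hi, lo_next):
                raise ValidationError("bands must be contiguous (partition [0,3])")
        if any(c < 0 for c in costs):
            raise ValidationError("band costs must be >= 0")
        # costs must be nondecreasing with worse (higher) HAQ-DI
        if any(a > b + 1e-9 for a, b in zip(costs, costs[1:])):
            raise ValidationError("band costs must be nondecreasing with severity")

    @property
    def costs(self) -> List[float]:
        return [b[2] for b in self.bands]

    @property
    def n_bands(self) -> int:
        return len(self.bands)


@dataclass(frozen=True)
class ItalianIndirectInputs:
    """Inputs for the Italian work-absence + early-retirement construction."""

    work_days_lost_per_employed: float = 0.0
    daily_average_income: float = 0.0
    employed_fraction: float = 0.0
    total_pension_costs: float = 0.0
    n_pensioners: int = 0
    pensioner_fraction: float = 0.0

    def __post_init__(self):
        for name in ("work_days_lost_per_employed", "daily_average_income",
                     "total_pension_costs"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        for name in ("employed_fraction", "pensioner_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValidationError(f"{name} must be in [0,1]")


#: Default conditional band mixes (fractions per band, rows sum to 1):
#: responders concentrate in milder HAQ bands, non-responders in worse ones.
DEFAULT_BAND_MIX: Dict[str, Tuple[float, ...]] = {
    "responder": (0.35, 0.30, 0.20, 0.10, 0.05),
    "non_responder": (0.05, 0.15, 0.25, 0.30, 0.25),
}


def distribute_cohort_to_bands(
    outcome: CohortOutcome,
    haq_response_rate: float,
    band_mix: Mapping[str, Sequence[float]],
) -> np.ndarray:
    """Allocate the cohort to HAQ bands via responder-conditional mixes.

    Returns expected (possibly fractional) per-band counts; they always sum
    to ``outcome.n`` because each mix row sums to 1 (validated at 1e-9).
    """
    if not 0.0 <= haq_response_rate <= 1.0:
        raise DomainError(f"haq_response_rate must be in [0,1], got {haq_response_rate}")
    mix_r = np.asarray(band_mix["responder"], dtype=float)
    mix_n = np.asarray(band_mix["non_responder"], dtype=float)
    if mix_r.shape != mix_n.shape:
        raise ValidationError("band mix rows must have equal length")
    for label, row in (("responder", mix_r), ("non_responder", mix_n)):
        if abs(row.sum() - 1.0) > 1e-9:
            raise ValidationError(f"band mix row {label!r} sums to {row.sum()}, not 1")
        if (row < 0).any():
            raise ValidationError(f"band mix row {label!r} has negative entries")
    responders = haq_response_rate * outcome.n
    return responders * mix_r + (outcome.n - responders) * mix_n


def societal_cost(
    band_counts: np.ndarray, schedule: HAQBandCostSchedule, horizon_years: float
) -> float:
    """Cohort societal cost: sum of band count x annual band cost x years."""
    if horizon_years < 0:
        raise DomainError(f"horizon_years must be >= 0, got {horizon_years}")
    counts = np.asarray(band_counts, dtype=float)
    costs = np.asarray(schedule.costs, dtype=float)
    if counts.shape != costs.shape:
        raise ValidationError(
            f"band count length {counts.shape} does not match schedule bands {costs.shape}"
        )
    return float(np.dot(counts, costs) * horizon_years)


def italian_indirect_per_patient(inputs: ItalianIndirectInputs) -> float:
    """Mean annual indirect cost per Italian RA patient.

    Employed fraction x (work days lost x daily average income) plus
    pensioner fraction x (total pension costs / number of pensioners).
    """
    pension_component = 0.0
    if inputs.total_pension_costs > 0 or inputs.pensioner_fraction > 0:
        if inputs.n_pensioners == 0:
            if inputs.total_pension_costs > 0:
                raise DomainError("n_pensioners = 0 with nonzero total pension costs")
        else:
            pension_component = inputs.pensioner_fraction * (
                inputs.total_pension_costs / inputs.n_pensioners
            )
    work_component = inputs.employed_fraction * (
        inputs.work_days_lost_per_employed * inputs.daily_average_income
    )
    return work_component + pension_component


def societal_cca(
    clinical: ClinicalInputTable,
    costs: CountryCostTable,
    resource_use: ResourceUseSchedule,
    safety: SafetyInputTable,
    subgroup: Subgroup,
    schedule: HAQBandCostSchedule,
    *,
    mode: str = "deterministic",
    seed: Optional[int] = None,
    band_mix: Optional[Mapping[str, Sequence[float]]] = None,
    horizon_weeks: float = 104.0,
    cohort_size: int = 1000,
    weight_kg: float = 80.5,
) -> CCAOutput:
    """Full CCA with the societal component added to each arm's breakdown.

    Only Germany and Italy carry bundled societal schedules; the schedule's
    country must match the cost table's.  With an all-zero schedule the
    result reduces bit-for-bit to the payer-perspective run.
    """
    if costs.country not in SOCIETAL_COUNTRIES:
        raise UnsupportedCountryError(
            f"societal perspective implemented for {SOCIETAL_COUNTRIES}, got {costs.country!r}"
        )
    if schedule.country != costs.country:
        raise ValidationError(
            f"schedule country {schedule.country} does not match cost table {costs.country}"
        )
    return full_cca(
        clinical,
        costs,
        resource_use,
        safety,
        subgroup,
        mode=mode,
        seed=seed,
        horizon_weeks=horizon_weeks,
        cohort_size=cohort_size,
        weight_kg=weight_kg,
        societal_schedule=schedule,
        band_mix=band_mix,
    )


__all__ = [
    "SOCIETAL_COUNTRIES",
    "HAQBandCostSchedule",
    "ItalianIndirectInputs",
    "DEFAULT_BAND_MIX",
    "distribute_cohort_to_bands",
    "societal_cost",
    "italian_indirect_per_patient",
    "societal_cca",
]
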