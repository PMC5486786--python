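"""Cost-consequence assembly: incremental cost per additional responder/remitter.

The headline quantity is the incremental cohort cost (abatacept minus
adalimumab) divided by the incremental number of responders (or patients in
remission) for each outcome measure, normalized per month of the 2-year
horizon.  Because the published figure's normalization is not recoverable,
both normalizations are always reported and labelled:

* ``cost_per_gain_pmpm`` — (incremental cost / incremental gain) / months;
* ``per_member_pmpm`` — incremental cost / (cohort size x months), the
  per-member-per-month budget view, which is defined even at zero gain.

A cost-consequence analysis does not collapse trade-offs into a single
ratio: cells where one arm is cheaper *and* at least as effective are
classified as favouring that arm; trade-off quadrants (more health for more
money, or less health for less money) and zero-gain ratios are flagged, never
silently ratioed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, NamedTuple, Optional

from .cohort_engine import (
    CohortOutcome,
    expected_counts,
    incremental_health_gain,
    sample_cohort,
)
from .cost_engine import CostBreakdown, arm_total_cost
from .exceptions import ComparabilityError, DomainError
from .inputs_io import (
    ARMS,
    ClinicalInputTable,
    CountryCostTable,
    OutcomeMeasure,
    ResourceUseSchedule,
    SafetyInputTable,
    Subgroup,
)


class PMPMValue(NamedTuple):
    """Both monthly normalizations of an incremental cost."""

    cost_per_gain: Optional[float]  # None when the gain is zero (indeterminate)
    per_member: float
    indeterminate: bool


@dataclass(frozen=True)
class IncrementalResult:
    """One outcome measure's incremental cost / health-gain cell."""

    subgroup: Subgroup
    measure: OutcomeMeasure
    incremental_cost: float  # cohort total, abatacept - adalimumab
    incremental_gain: int
    cost_per_gain_pmpm: Optional[float]
    per_member_pmpm: float
    favours: str  # abatacept | adalimumab | indeterminate
    indeterminate_ratio: bool


def incremental_cost(a: CostBreakdown, b: CostBreakdown) -> float:
    """Total cohort cost difference ``a - b`` (exact in minor currency units)."""
    if a.currency != b.currency:
        raise ComparabilityError(f"currency mismatch: {a.currency} vs {b.currency}")
    if a.n != b.n:
        raise ComparabilityError(f"cohort size mismatch: {a.n} vs {b.n}")
    return (a.total_cents - b.total_cents) / 100.0


def cost_per_gain_pmpm(
    incremental_cost: float, incremental_gain: int, n: int, horizon_months: float
) -> PMPMValue:
    """Monthly incremental cost per health gain, plus the per-member companion.

    Zero gain is an indeterminate ratio (flagged, not an exception); the
    per-member value is always defined.  A zero incremental cost gives 0
    regardless of the gain's sign.
    """
    if horizon_months <= 0:
        raise DomainError(f"horizon_months must be > 0, got {horizon_months}")
    if n <= 0:
        raise DomainError(f"n must be > 0, got {n}")
    per_member = incremental_cost / (n * horizon_months)
    if incremental_gain == 0:
        if incremental_cost == 0:
            return PMPMValue(cost_per_gain=0.0, per_member=per_member, indeterminate=False)
        return PMPMValue(cost_per_gain=None, per_member=per_member, indeterminate=True)
    return PMPMValue(
        cost_per_gain=incremental_cost / incremental_gain / horizon_months,
        per_member=per_member,
        indeterminate=False,
    )


def classify_favours(incremental_cost: float, incremental_gain: float) -> str:
    """Dominance classification of a (cost, gain) cell.

    abatacept: cheaper with at least equal health, or equal cost with more
    health; adalimumab: the mirror image; anything else (trade-offs, exact
    ties) is indeterminate and left to the decision-maker.
    """
    if (incremental_cost < 0 and incremental_gain >= 0) or (
        incremental_cost <= 0 and incremental_gain > 0
    ):
        return "abatacept"
    if (incremental_cost > 0 and incremental_gain <= 0) or (
        incremental_cost >= 0 and incremental_gain < 0
    ):
        return "adalimumab"
    return "indeterminate"


@dataclass(frozen=True)
class CCAOutput:
    """Everything one model evaluation produces."""

    subgroup: Subgroup
    results: List[IncrementalResult]
    outcomes: Dict[str, CohortOutcome]
    breakdowns: Dict[str, CostBreakdown]
    incremental_total: float
    horizon_months: float
    perspective: str


def full_cca(
    clinical: ClinicalInputTable,
    costs: CountryCostTable,
    resource_use: ResourceUseSchedule,
    safety: SafetyInputTable,
    subgroup: Subgroup,
    *,
    mode: str = "deterministic",
    seed: Optional[int] = None,
    horizon_weeks: float = 104.0,
    cohort_size: int = 1000,
    weight_kg: float = 80.5,
    prorate_discontinuation: bool = False,
    societal_schedule=None,
    band_mix=None,
) -> CCAOutput:
    """Run the complete cost-consequence analysis for one subgroup.

    Returns one :class:`IncrementalResult` per outcome measure present in the
    clinical table (8 with the bundled fixture), with safety tallies echoed in
    ``outcomes``.  Deterministic mode is exactly reproducible; stochastic mode
    draws per-arm binomial tallies from ``seed``.

    With ``societal_schedule`` (a HAQ-band cost schedule for DE or IT) each
    arm's breakdown gains a societal component allocated by HAQ-DI response
    (see :mod:`rheumcca.societal`).
    """
    if mode not in ("deterministic", "stochastic"):
        raise DomainError(f"mode must be deterministic|stochastic, got {mode!r}")

    outcomes: Dict[str, CohortOutcome] = {}
    for i, arm in enumerate(ARMS):
        if mode == "deterministic":
            outcomes[arm] = expected_counts(clinical, safety, subgroup, arm, cohort_size)
        else:
            if seed is None:
                raise DomainError("stochastic mode requires a seed")
            outcomes[arm] = sample_cohort(
                clinical, safety, subgroup, arm, cohort_size, seed + i
            )

    horizon_years = horizon_weeks / 52.0
    breakdowns: Dict[str, CostBreakdown] = {}
    for arm in ARMS:
        societal_component = None
        if societal_schedule is not None:
            from .societal import DEFAULT_BAND_MIX, distribute_cohort_to_bands, societal_cost

            mix = band_mix if band_mix is not None else DEFAULT_BAND_MIX
            haq_rate = outcomes[arm].rate(OutcomeMeasure.HAQ_DI)
            band_counts = distribute_cohort_to_bands(outcomes[arm], haq_rate, mix)
            societal_component = societal_cost(band_counts, societal_schedule, horizon_years)
        breakdowns[arm] = arm_total_cost(
            outcomes[arm],
            costs,
            resource_use,
            horizon_weeks,
            weight_kg,
            prorate_discontinuation=prorate_discontinuation,
            societal_component=societal_component,
        )

    inc_cost = incremental_cost(breakdowns["abatacept"], breakdowns["adalimumab"])
    horizon_months = horizon_weeks / 52.0 * 12.0
    results = []
    measures = [
        m for m in OutcomeMeasure
        if all((subgroup, arm, m) in clinical.proportions for arm in ARMS)
    ]
    for m in measures:
        gain = incremental_health_gain(outcomes["abatacept"], outcomes["adalimumab"], m)
        pm = cost_per_gain_pmpm(inc_cost, gain, cohort_size, horizon_months)
        results.append(
            IncrementalResult(
                subgroup=subgroup,
                measure=m,
                incremental_cost=inc_cost,
                incremental_gain=gain,
                cost_per_gain_pmpm=pm.cost_per_gain,
                per_member_pmpm=pm.per_member,
                favours=classify_favours(inc_cost, gain),
                indeterminate_ratio=pm.indeterminate,
            )
        )
    return CCAOutput(
        subgroup=subgroup,
        results=results,
        outcomes=outcomes,
        breakdowns=breakdowns,
        incremental_total=inc_cost,
        horizon_months=horizon_months,
        perspective="societal" if societal_schedule is not None else "payer",
    )


__all__ = [
    "PMPMValue",
    "IncrementalResult",
    "CCAOutput",
    "incremental_cost",
    "cost_per_gain_pmpm",
    "classify_favours",
    "full_cca",
]
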