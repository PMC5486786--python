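"""Decision-tree cohort engine.

Turns clinical and safety input rates into per-arm counts of responders,
remitters, discontinuations and safety events for a cohort of configurable
size (default 1000 patients, the size the published model simulated).

Branches are marginal (independent) tallies: each outcome's count is computed
from its own input rate, not from a joint patient-level state — the published
tree reports only marginal counts, and serious adverse events and injection
site reactions are treated as mutually exclusive branches tallied separately.
Discontinuation is itself an outcome measure and does not truncate the
response tallies (intention-to-treat accounting).

Two modes:

* deterministic — expected counts, ``round-half-up(rate * n)``;
* stochastic — one binomial draw per branch, reproducible given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping

import numpy as np

from ._util import round_half_up_int
from .exceptions import ComparabilityError, DomainError
from .inputs_io import (
    ClinicalInputTable,
    OutcomeMeasure,
    SafetyInputTable,
    Subgroup,
    DISCONTINUATION_CLASSES,
)


@dataclass(frozen=True)
class CohortOutcome:
    """Per-arm event counts for one subgroup and cohort size."""

    arm: str
    subgroup: Subgroup
    n: int
    responders: Mapping[OutcomeMeasure, int]
    discontinuations: Mapping[str, int]
    safety_events: Mapping[str, int]

    def __post_init__(self):
        for label, counts in (
            ("responders", self.responders),
            ("discontinuations", self.discontinuations),
            ("safety_events", self.safety_events),
        ):
            for key, c in counts.items():
                if not 0 <= c <= self.n:
                    name = getattr(key, "value", key)
                    raise DomainError(
                        f"{label}[{name}] = {c} outside [0, n={self.n}]"
                    )

    def rate(self, measure: OutcomeMeasure) -> float:
        return self.responders[measure] / self.n


def _require_clinical(clinical: ClinicalInputTable, subgroup: Subgroup, arm: str):
    if not any((sg, a) == (subgroup, arm) for (sg, a, _m) in clinical.proportions):
        from .exceptions import MissingInputError

        raise MissingInputError(
            f"no clinical inputs for ({subgroup.value}, {arm})"
        )


def _split_events(safety: SafetyInputTable, subgroup: Subgroup, arm: str):
    events = safety.events(subgroup, arm)
    disc = [e for e in events if e in DISCONTINUATION_CLASSES]
    other = [e for e in events if e not in DISCONTINUATION_CLASSES]
    return disc, other


def expected_counts(
    clinical: ClinicalInputTable,
    safety: SafetyInputTable,
    subgroup: Subgroup,
    arm: str,
    n: int,
) -> CohortOutcome:
    """Deterministic branch tallies: each count is round-half-up(rate * n)."""
    if n <= 0:
        raise DomainError(f"cohort size must be > 0, got {n}")
    _require_clinical(clinical, subgroup, arm)
    responders = {
        m: round_half_up_int(clinical.proportion(subgroup, arm, m) * n)
        for m in OutcomeMeasure
        if (subgroup, arm, m) in clinical.proportions
    }
    disc_events, other_events = _split_events(safety, subgroup, arm)
    discontinuations = {
        e: round_half_up_int(safety.rate(subgroup, arm, e) * n) for e in disc_events
    }
    safety_events = {
        e: round_half_up_int(safety.rate(subgroup, arm, e) * n) for e in other_events
    }
    return CohortOutcome(
        arm=arm,
        subgroup=subgroup,
        n=n,
        responders=responders,
        discontinuations=discontinuations,
        safety_events=safety_events,
    )


def sample_cohort(
    clinical: ClinicalInputTable,
    safety: SafetyInputTable,
    subgroup: Subgroup,
    arm: str,
    n: int,
    seed: int,
) -> CohortOutcome:
    """Stochastic tallies: one Binomial(n, rate) draw per branch.

    Branches are drawn in a fixed (sorted) order from a single
    ``numpy.random.default_rng(seed)`` stream, so identical seeds give
    identical outcomes.
    """
    if n <= 0:
        raise DomainError(f"cohort size must be > 0, got {n}")
    _require_clinical(clinical, subgroup, arm)
    rng = np.random.default_rng(seed)
    responders = {}
    for m in OutcomeMeasure:  # enum order is fixed
        if (subgroup, arm, m) in clinical.proportions:
            responders[m] = int(rng.binomial(n, clinical.proportion(subgroup, arm, m)))
    disc_events, other_events = _split_events(safety, subgroup, arm)
    discontinuations = {
        e: int(rng.binomial(n, safety.rate(subgroup, arm, e))) for e in disc_events
    }
    safety_events = {
        e: int(rng.binomial(n, safety.rate(subgroup, arm, e))) for e in other_events
    }
    return CohortOutcome(
        arm=arm,
        subgroup=subgroup,
        n=n,
        responders=responders,
        discontinuations=discontinuations,
        safety_events=safety_events,
    )


def incremental_health_gain(
    a: CohortOutcome, b: CohortOutcome, measure: OutcomeMeasure
) -> int:
    """Responder-count difference ``a - b`` (abatacept minus adalimumab by convention).

    Negative gains are permitted and meaningful.
    """
    if a.n != b.n:
        raise ComparabilityError(f"cohort sizes differ: {a.n} vs {b.n}")
    if a.subgroup != b.subgroup:
        raise ComparabilityError(
            f"subgroups differ: {a.subgroup.value} vs {b.subgroup.value}"
        )
    return a.responders[measure] - b.responders[measure]


__all__ = ["CohortOutcome", "expected_counts", "sample_cohort", "incremental_health_gain"]
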