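"""Model/Results interface tying the pipeline together.

:class:`CostConsequenceModel` is constructed from the four input tables (or a
deck directory, or the bundled fixtures), holds the run configuration, and
exposes:

* ``fit(mode=..., seed=...)`` -> :class:`CCAResults` with the per-arm cohort
  outcomes, cost breakdowns, the incremental table and a ``summary()``;
* ``sensitivity(...)`` -> :class:`TornadoResults` with the one-way
  sensitivity entries ranked by impact on the total incremental cost.

Example
-------
>>> from rheumcca import CostConsequenceModel, Subgroup
>>> model = CostConsequenceModel.from_fixtures("DE", Subgroup.Q4)
>>> res = model.fit()
>>> print(res.summary())            # doctest: +SKIP
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, replace
from typing import Dict, List, Mapping, Optional, Sequence

import pandas as pd

from .cca import CCAOutput, full_cca
from .exceptions import DomainError, UnsupportedCountryError
from .inputs_io import (
    ARMS,
    ClinicalInputTable,
    CountryCostTable,
    DrugCost,
    InputDeck,
    ResourceUseSchedule,
    SafetyInputTable,
    Subgroup,
    load_input_deck,
    table1_fixture,
    table2_fixture,
)
from .owsa import ParameterSpec, TornadoEntry, run_owsa
from .synthetic_inputs import (
    SyntheticScenario,
    default_safety_fixture,
    generate_haq_cost_schedule,
    generate_resource_use,
)


class CostConsequenceModel:
    """Decision-tree cost-consequence model for one country and ACPA subgroup.

    Parameters
    ----------
    clinical, costs, resource_use, safety
        The four validated input tables.
    subgroup
        ACPA subgroup to analyse.
    horizon_weeks, cohort_size, weight_kg
        Run configuration; defaults 104 weeks, 1000 patients, 80.5 kg.
    perspective
        "payer" (default) or "societal"; the societal perspective needs a
        HAQ-band cost schedule (bundled synthetic defaults exist for DE/IT).
    """

    def __init__(
        self,
        clinical: ClinicalInputTable,
        costs: CountryCostTable,
        resource_use: ResourceUseSchedule,
        safety: SafetyInputTable,
        subgroup: Subgroup,
        *,
        horizon_weeks: float = 104.0,
        cohort_size: int = 1000,
        weight_kg: float = 80.5,
        perspective: str = "payer",
        haq_schedule=None,
        band_mix=None,
        prorate_discontinuation: bool = False,
    ):
        if horizon_weeks <= 0:
            raise DomainError(f"horizon_weeks must be > 0, got {horizon_weeks}")
        if cohort_size <= 0:
            raise DomainError(f"cohort_size must be > 0, got {cohort_size}")
        if perspective not in ("payer", "societal"):
            raise DomainError(f"perspective must be payer|societal, got {perspective!r}")
        if perspective == "societal" and haq_schedule is None:
            haq_schedule = generate_haq_cost_schedule(
                costs.country, SyntheticScenario(seed=0)
            )
        self.clinical = clinical
        self.costs = costs
        self.resource_use = resource_use
        self.safety = safety
        self.subgroup = subgroup
        self.horizon_weeks = horizon_weeks
        self.cohort_size = cohort_size
        self.weight_kg = weight_kg
        self.perspective = perspective
        self.haq_schedule = haq_schedule
        self.band_mix = band_mix
        self.prorate_discontinuation = prorate_discontinuation

    # ----------------------------------------------------------- constructors

    @classmethod
    def from_fixtures(
        cls,
        country: str,
        subgroup: Subgroup,
        *,
        scenario: Optional[SyntheticScenario] = None,
        **config,
    ) -> "CostConsequenceModel":
        """Model on the bundled printed tables plus synthetic defaults.

        Clinical inputs and unit costs come from the bundled fixtures; safety
        incidences from the reported per-1000 counts (plus documented
        defaults); resource use from the package defaults filtered to the
        country's priced drugs.
        """
        scenario = scenario or SyntheticScenario(seed=0)
        return cls(
            clinical=table1_fixture(),
            costs=table2_fixture(country),
            resource_use=generate_resource_use(scenario, country=country),
            safety=default_safety_fixture(),
            subgroup=subgroup,
            **config,
        )

    @classmethod
    def from_deck(cls, path, subgroup: Subgroup, **config) -> "CostConsequenceModel":
        """Model from a deck directory (see :mod:`rheumcca.inputs_io`)."""
        deck = load_input_deck(path)
        return cls(
            clinical=deck.clinical,
            costs=deck.costs,
            resource_use=deck.resource_use,
            safety=deck.safety,
            subgroup=subgroup,
            **config,
        )

    # ------------------------------------------------------------------- fit

    def fit(self, mode: str = "deterministic", seed: Optional[int] = None) -> "CCAResults":
        """Evaluate the model; deterministic mode is exactly reproducible."""
        out = full_cca(
            self.clinical,
            self.costs,
            self.resource_use,
            self.safety,
            self.subgroup,
            mode=mode,
            seed=seed,
            horizon_weeks=self.horizon_weeks,
            cohort_size=self.cohort_size,
            weight_kg=self.weight_kg,
            prorate_discontinuation=self.prorate_discontinuation,
            societal_schedule=self.haq_schedule if self.perspective == "societal" else None,
            band_mix=self.band_mix,
        )
        return CCAResults(model=self, output=out, mode=mode, seed=seed)

    # ----------------------------------------------------------- sensitivity

    def parameter_specs(self) -> List[ParameterSpec]:
        """Default OWSA parameter set for the payer-perspective incremental cost.

        Varied: biologic unit prices, monitoring frequencies and unit costs,
        AE management tariffs, and safety incidences for both arms.  Fixed by
        rule: horizon, dose schedules, concomitant drug prices, cohort size
        and patient weight (point quantities not subject to parameter
        uncertainty); zero-mean parameters never vary.
        """
        specs: List[ParameterSpec] = []
        for arm in ARMS:
            specs.append(
                ParameterSpec(
                    id=f"price.{arm}",
                    value=self.costs.drug(arm).unit_price,
                    kind="continuous",
                )
            )
        for name in sorted(self.costs.drugs):
            if name not in ARMS:
                specs.append(
                    ParameterSpec(
                        id=f"price.{name}",
                        value=self.costs.drugs[name].unit_price,
                        kind="fixed",
                        varies=False,
                    )
                )
        for item, cost in sorted(self.costs.monitoring_unit_costs.items()):
            specs.append(
                ParameterSpec(id=f"monitoring_cost.{item}", value=cost, kind="continuous")
            )
        r = self.resource_use
        for item, rate in (
            ("outpatient_visits_per_year", r.outpatient_visits_per_year),
            ("radiographs_per_year", r.radiographs_per_year),
            ("blood_test_series_per_year", r.blood_test_series_per_year),
        ):
            specs.append(
                ParameterSpec(id=f"monitoring_rate.{item}", value=rate, kind="continuous")
            )
        for item, cost in sorted(self.costs.ae_class_costs.items()):
            specs.append(ParameterSpec(id=f"ae_cost.{item}", value=cost, kind="continuous"))
        for item, cost in sorted(self.costs.frequent_ae_costs.items()):
            specs.append(ParameterSpec(id=f"ae_cost.{item}", value=cost, kind="continuous"))
        for arm in ARMS:
            for event in self.safety.events(self.subgroup, arm):
                specs.append(
                    ParameterSpec(
                        id=f"incidence.{event}.{arm}",
                        value=self.safety.rate(self.subgroup, arm, event),
                        kind="proportion",
                    )
                )
        return specs

    def _with_overrides(self, overrides: Mapping[str, float]) -> "CostConsequenceModel":
        """A copy of the model with parameter overrides applied by id."""
        costs = self.costs
        safety = self.safety
        resource_use = self.resource_use
        drugs = dict(costs.drugs)
        monitoring = dict(costs.monitoring_unit_costs)
        ae_class = dict(costs.ae_class_costs)
        ae_item = dict(costs.frequent_ae_costs)
        incidence = dict(safety.incidence)
        ru_kwargs = {
            "outpatient_visits_per_year": resource_use.outpatient_visits_per_year,
            "radiographs_per_year": resource_use.radiographs_per_year,
            "blood_test_series_per_year": resource_use.blood_test_series_per_year,
            "concomitant_regimen": resource_use.concomitant_regimen,
        }
        for pid, value in overrides.items():
            domain, _, rest = pid.partition(".")
            if domain == "price":
                drugs[rest] = dataclasses.replace(drugs[rest], unit_price=float(value))
            elif domain == "monitoring_cost":
                monitoring[rest] = float(value)
            elif domain == "monitoring_rate":
                ru_kwargs[rest] = float(value)
            elif domain == "ae_cost":
                if rest in ae_class:
                    ae_class[rest] = float(value)
                else:
                    ae_item[rest] = float(value)
            elif domain == "incidence":
                event, _, arm = rest.rpartition(".")
                key = (self.subgroup, arm, event)
                if key not in incidence:
                    raise DomainError(f"unknown incidence override {pid!r}")
                incidence[key] = float(value)
            else:
                raise DomainError(f"unknown parameter id {pid!r}")
        new_costs = dataclasses.replace(
            costs,
            drugs=drugs,
            monitoring_unit_costs=monitoring,
            ae_class_costs=ae_class,
            frequent_ae_costs=ae_item,
        )
        new = CostConsequenceModel(
            clinical=self.clinical,
            costs=new_costs,
            resource_use=ResourceUseSchedule(**ru_kwargs),
            safety=SafetyInputTable(incidence=incidence),
            subgroup=self.subgroup,
            horizon_weeks=self.horizon_weeks,
            cohort_size=self.cohort_size,
            weight_kg=self.weight_kg,
            perspective=self.perspective,
            haq_schedule=self.haq_schedule,
            band_mix=self.band_mix,
            prorate_discontinuation=self.prorate_discontinuation,
        )
        return new

    def incremental_cost_at(self, overrides: Mapping[str, float]) -> float:
        """Deterministic total incremental cost with the given overrides."""
        return self._with_overrides(overrides).fit(mode="deterministic").incremental_total

    def sensitivity(
        self, params: Optional[Sequence[ParameterSpec]] = None, top: Optional[int] = None
    ) -> "TornadoResults":
        """One-way sensitivity analysis around the deterministic baseline."""
        specs = list(params) if params is not None else self.parameter_specs()
        entries = run_owsa(self.incremental_cost_at, specs)
        baseline = self.incremental_cost_at({})
        return TornadoResults(model=self, entries=entries, baseline=baseline, top=top)


@dataclass(frozen=True)
class CCAResults:
    """Fitted cost-consequence results with summary and export helpers."""

    model: CostConsequenceModel
    output: CCAOutput
    mode: str
    seed: Optional[int]

    @property
    def results(self):
        return self.output.results

    @property
    def outcomes(self):
        return self.output.outcomes

    @property
    def breakdowns(self):
        return self.output.breakdowns

    @property
    def incremental_total(self) -> float:
        return self.output.incremental_total

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.results:
            rows.append(
                {
                    "subgroup": r.subgroup.value,
                    "measure": r.measure.value,
                    "incremental_gain": r.incremental_gain,
                    "incremental_cost": r.incremental_cost,
                    "cost_per_gain_pmpm": r.cost_per_gain_pmpm,
                    "per_member_pmpm": r.per_member_pmpm,
                    "favours": r.favours,
                    "indeterminate_ratio": r.indeterminate_ratio,
                }
            )
        return pd.DataFrame(rows)

    def costs_frame(self) -> pd.DataFrame:
        rows = []
        for arm, b in self.breakdowns.items():
            row = {"arm": arm, "currency": b.currency, **b.components, "total": b.total}
            rows.append(row)
        return pd.DataFrame(rows)

    def summary(self) -> str:
        m = self.model
        lines = [
            "Cost-consequence analysis: abatacept vs adalimumab",
            "=" * 64,
            f"Country: {m.costs.country} ({m.costs.currency}, "
            f"price year {m.costs.price_year})   Subgroup: {m.subgroup.value}",
            f"Cohort: {m.cohort_size} per arm   Horizon: {m.horizon_weeks:g} weeks"
            f"   Perspective: {self.output.perspective}   Mode: {self.mode}"
            + (f" (seed={self.seed})" if self.seed is not None else ""),
            "",
            "Cohort costs by component",
            "-" * 64,
            self.costs_frame().to_string(index=False, float_format=lambda v: f"{v:,.2f}"),
            "",
            f"Total incremental cost (abatacept - adalimumab): "
            f"{self.incremental_total:,.2f} {m.costs.currency}",
            "",
            "Incremental cost per health gain (per month of horizon)",
            "-" * 64,
            self.to_frame().to_string(
                index=False,
                float_format=lambda v: f"{v:,.2f}",
                na_rep="indeterminate",
            ),
        ]
        return "\n".join(lines)


@dataclass(frozen=True)
class TornadoResults:
    """Ranked one-way sensitivity entries."""

    model: CostConsequenceModel
    entries: List[TornadoEntry]
    baseline: float
    top: Optional[int] = None

    def top_entries(self, n: Optional[int] = None) -> List[TornadoEntry]:
        n = n if n is not None else (self.top or 10)
        return self.entries[:n]

    def to_frame(self, top: Optional[int] = None) -> pd.DataFrame:
        entries = self.entries if top is None else self.top_entries(top)
        return pd.DataFrame(
            [
                {
                    "parameter": e.parameter,
                    "low_value": e.low_value,
                    "high_value": e.high_value,
                    "low_result": e.low_result,
                    "high_result": e.high_result,
                    "range": e.range,
                    "crosses_zero": e.crosses_zero,
                    "failed": e.failed,
                }
                for e in entries
            ]
        )

    def summary(self) -> str:
        m = self.model
        return "\n".join(
            [
                "One-way sensitivity analysis on total incremental cost",
                "=" * 64,
                f"Country: {m.costs.country}   Subgroup: {m.subgroup.value}   "
                f"Baseline: {self.baseline:,.2f} {m.costs.currency}",
                "",
                self.to_frame(self.top or 10).to_string(
                    index=False, float_format=lambda v: f"{v:,.2f}"
                ),
            ]
        )


__all__ = ["CostConsequenceModel", "CCAResults", "TornadoResults"]
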