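"""Domain types, validation and deck I/O for the cost-consequence model.

The model consumes four tables — clinical response/remission proportions,
per-country unit costs, resource-use frequencies, and safety/discontinuation
incidences — stored on disk as a "deck": a directory of four comma-separated
files (``clinical.csv``, ``costs.csv``, ``resource_use.csv``, ``safety.csv``).
Percentages in decks are stored as printed percentages and converted to
fractions on load, so a deck can be diffed directly against a published table.

Bundled fixtures: :func:`table1_fixture` (clinical inputs for the ACPA-negative,
ACPA-positive, first- and fourth-quartile subgroups of the head-to-head trial)
and :func:`table2_fixture` (drug and monitoring unit costs for DE/IT/ES/US/CA,
plus *synthetic* adverse-event management tariffs — see :mod:`rheumcca._tables`).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Mapping, NamedTuple, Optional, Sequence, Tuple

import pandas as pd

from . import _tables
from ._util import round_half_up
from .exceptions import (
    DeckIncompleteError,
    DomainError,
    UnsupportedCountryError,
    ValidationError,
)

ARMS = ("abatacept", "adalimumab")
COUNTRIES = ("DE", "IT", "ES", "US", "CA")

DECK_FILES = ("clinical.csv", "costs.csv", "resource_use.csv", "safety.csv")


class Subgroup(enum.Enum):
    """ACPA serostatus subgroups with their serum-titre intervals (AU/mL).

    Negativity is defined as a titre below 25 AU/mL; positive patients are
    additionally split into four empirical quartiles.  The printed quartile
    bounds leave small gaps (25-27, 610-612, 1047-1059, >4894); titres falling
    in a gap are assigned to the nearest quartile, ties to the lower quartile
    (a documented convention so that every titre has a subgroup).
    """

    ACPA_NEG = "ACPA_NEG"
    ACPA_POS = "ACPA_POS"
    Q1 = "Q1"
    Q2 = "Q2"
    Q3 = "Q3"
    Q4 = "Q4"


#: Closed titre intervals as printed; ACPA_NEG is [0, 25) and ACPA_POS [25, inf).
TITRE_RANGES: Dict[Subgroup, Tuple[float, float]] = {
    Subgroup.ACPA_NEG: (0.0, 25.0),
    Subgroup.ACPA_POS: (25.0, math.inf),
    Subgroup.Q1: (28.0, 235.0),
    Subgroup.Q2: (236.0, 609.0),
    Subgroup.Q3: (613.0, 1046.0),
    Subgroup.Q4: (1060.0, 4894.0),
}

QUARTILES = (Subgroup.Q1, Subgroup.Q2, Subgroup.Q3, Subgroup.Q4)


class OutcomeMeasure(enum.Enum):
    """Clinical efficacy outcomes carried by the model.

    Five response measures (ACR 20/50/70/90% improvement and a HAQ-DI
    improvement of at least 0.3 units) and three remission measures
    (DAS28-CRP < 2.6, CDAI <= 2.8, SDAI <= 3.3).
    """

    ACR20 = "ACR20"
    ACR50 = "ACR50"
    ACR70 = "ACR70"
    ACR90 = "ACR90"
    HAQ_DI = "HAQ_DI"
    DAS28_REMISSION = "DAS28_REMISSION"
    CDAI_REMISSION = "CDAI_REMISSION"
    SDAI_REMISSION = "SDAI_REMISSION"

    @property
    def kind(self) -> str:
        return "remission" if self.name.endswith("_REMISSION") else "response"

    @property
    def threshold_note(self) -> str:
        return _THRESHOLD_NOTES[self]


_THRESHOLD_NOTES = {
    OutcomeMeasure.ACR20: ">=20% ACR core-set improvement",
    OutcomeMeasure.ACR50: ">=50% ACR core-set improvement",
    OutcomeMeasure.ACR70: ">=70% ACR core-set improvement",
    OutcomeMeasure.ACR90: ">=90% ACR core-set improvement",
    OutcomeMeasure.HAQ_DI: "HAQ-DI improvement >=0.3 units",
    OutcomeMeasure.DAS28_REMISSION: "DAS28-CRP < 2.6",
    OutcomeMeasure.CDAI_REMISSION: "CDAI <= 2.8",
    OutcomeMeasure.SDAI_REMISSION: "SDAI <= 3.3",
}

RESPONSE_MEASURES = tuple(m for m in OutcomeMeasure if m.kind == "response")
REMISSION_MEASURES = tuple(m for m in OutcomeMeasure if m.kind == "remission")

_ACR_LADDER = (
    OutcomeMeasure.ACR20,
    OutcomeMeasure.ACR50,
    OutcomeMeasure.ACR70,
    OutcomeMeasure.ACR90,
)

# Safety/discontinuation event classes carried by the safety table beyond the
# named frequent-AE types.
SAFETY_CLASSES = (
    "SAE",
    "LISR",
    "malignancy",
    "autoimmune",
    "discontinuation_any",
    "discontinuation_efficacy",
    "discontinuation_safety",
)
DISCONTINUATION_CLASSES = (
    "discontinuation_any",
    "discontinuation_efficacy",
    "discontinuation_safety",
)


# --------------------------------------------------------------------------
# container types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ClinicalInputTable:
    """Response/remission proportions per (subgroup, arm, outcome) with arm sizes."""

    proportions: Mapping[Tuple[Subgroup, str, OutcomeMeasure], float]
    arm_n: Mapping[Tuple[Subgroup, str], int]

    def __post_init__(self):
        for key, p in self.proportions.items():
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"clinical proportion out of [0,1] at {_kfmt(key)}: {p}")
        for key, n in self.arm_n.items():
            if n <= 0:
                raise ValidationError(f"arm size must be positive at {_kfmt(key)}: {n}")
        self._check_acr_monotone()

    def _check_acr_monotone(self):
        for (sg, arm) in {(sg, arm) for (sg, arm, _m) in self.proportions}:
            ladder = [
                self.proportions.get((sg, arm, m)) for m in _ACR_LADDER
            ]
            known = [p for p in ladder if p is not None]
            if any(a < b - 1e-12 for a, b in zip(known, known[1:])):
                raise ValidationError(
                    f"ACR monotonicity violated (ACR20>=50>=70>=90) for "
                    f"({sg.value}, {arm}): {known}"
                )

    def proportion(self, subgroup: Subgroup, arm: str, measure: OutcomeMeasure) -> float:
        try:
            return self.proportions[(subgroup, arm, measure)]
        except KeyError:
            from .exceptions import MissingInputError

            raise MissingInputError(
                f"no clinical input for ({subgroup.value}, {arm}, {measure.value})"
            ) from None

    def n(self, subgroup: Subgroup, arm: str) -> int:
        try:
            return self.arm_n[(subgroup, arm)]
        except KeyError:
            from .exceptions import MissingInputError

            raise MissingInputError(f"no arm size for ({subgroup.value}, {arm})") from None

    def subgroups(self) -> List[Subgroup]:
        return sorted({sg for (sg, _a) in self.arm_n}, key=lambda s: s.value)


@dataclass(frozen=True)
class DoseSchedule:
    """Posology of a study drug: dose per administration and dosing interval."""

    dose_mg: float
    interval_weeks: float
    route: str = "subcutaneous"
    per_kg: bool = False

    def __post_init__(self):
        if self.dose_mg <= 0:
            raise ValidationError(f"dose_mg must be > 0, got {self.dose_mg}")
        if self.interval_weeks <= 0:
            raise ValidationError(f"interval_weeks must be > 0, got {self.interval_weeks}")
        if self.route not in ("subcutaneous", "oral"):
            raise ValidationError(f"route must be subcutaneous|oral, got {self.route!r}")


@dataclass(frozen=True)
class DrugCost:
    """Unit pricing of a drug: milligrams per priced unit and price per unit."""

    name: str
    unit_size_mg: float
    unit_price: float
    route: str = "oral"
    schedule: Optional[DoseSchedule] = None
    printed_price_per_mg: Optional[float] = None

    def __post_init__(self):
        if self.unit_size_mg <= 0:
            raise ValidationError(f"{self.name}: unit_size_mg must be > 0")
        if self.unit_price < 0:
            raise ValidationError(f"{self.name}: unit_price must be >= 0")

    @property
    def price_per_mg(self) -> float:
        return price_per_mg(self.unit_price, self.unit_size_mg)


@dataclass(frozen=True)
class CountryCostTable:
    """All unit costs for one country: drugs, monitoring, AE management.

    ``ae_class_costs`` prices the event classes (frequent_AE, LISR, SAE,
    malignancy, autoimmune); ``frequent_ae_costs`` optionally prices named
    frequent-AE types individually.  AEs observed outside the named list are
    aggregated under "other AEs" and priced at the average of the named
    frequent-AE tariffs (:meth:`other_ae_cost`).
    """

    country: str
    currency: str
    price_year: int
    drugs: Mapping[str, DrugCost]
    monitoring_unit_costs: Mapping[str, float]
    ae_class_costs: Mapping[str, float]
    frequent_ae_costs: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for item, cost in {**self.monitoring_unit_costs, **self.ae_class_costs,
                           **self.frequent_ae_costs}.items():
            if cost < 0:
                raise ValidationError(f"{self.country}: unit cost for {item} must be >= 0")
        expected = {"DE": "EUR", "IT": "EUR", "ES": "EUR", "US": "USD", "CA": "CAD"}
        if self.country in expected and self.currency != expected[self.country]:
            raise ValidationError(
                f"currency {self.currency} does not match country {self.country}"
            )

    def drug(self, name: str) -> DrugCost:
        try:
            return self.drugs[name]
        except KeyError:
            from .exceptions import MissingPriceError

            raise MissingPriceError(
                f"drug {name!r} is not priced for {self.country}"
            ) from None

    def other_ae_cost(self) -> float:
        """Average of the named frequent-AE tariffs (fallback: frequent_AE class)."""
        if self.frequent_ae_costs:
            vals = list(self.frequent_ae_costs.values())
            return sum(vals) / len(vals)
        return self.ae_class_costs["frequent_AE"]


@dataclass(frozen=True)
class ResourceUseSchedule:
    """Disease-monitoring frequencies and the concomitant drug regimen.

    ``concomitant_regimen`` entries are (drug name, mg per day, fraction of the
    cohort exposed).
    """

    outpatient_visits_per_year: float
    radiographs_per_year: float
    blood_test_series_per_year: float
    concomitant_regimen: Sequence[Tuple[str, float, float]] = ()

    def __post_init__(self):
        for label, rate in (
            ("outpatient_visits_per_year", self.outpatient_visits_per_year),
            ("radiographs_per_year", self.radiographs_per_year),
            ("blood_test_series_per_year", self.blood_test_series_per_year),
        ):
            if rate < 0:
                raise ValidationError(f"{label} must be >= 0, got {rate}")
        for name, mg_per_day, exposure in self.concomitant_regimen:
            if mg_per_day < 0:
                raise ValidationError(f"concomitant {name}: mg_per_day must be >= 0")
            if not 0.0 <= exposure <= 1.0:
                raise ValidationError(f"concomitant {name}: exposure must be in [0,1]")


@dataclass(frozen=True)
class SafetyInputTable:
    """Incidences (2-year risks) per (subgroup, arm, event class)."""

    incidence: Mapping[Tuple[Subgroup, str, str], float]

    def __post_init__(self):
        for key, p in self.incidence.items():
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"safety incidence out of [0,1] at {_kfmt(key)}: {p}")
        # discontinuation for any reason must dominate its cause-specific parts
        pairs = {(sg, arm) for (sg, arm, _e) in self.incidence}
        for sg, arm in pairs:
            any_ = self.incidence.get((sg, arm, "discontinuation_any"))
            if any_ is None:
                continue
            for cause in ("discontinuation_efficacy", "discontinuation_safety"):
                part = self.incidence.get((sg, arm, cause), 0.0)
                if part > any_ + 1e-12:
                    raise ValidationError(
                        f"discontinuation_any < {cause} for ({sg.value}, {arm})"
                    )

    def rate(self, subgroup: Subgroup, arm: str, event: str) -> float:
        try:
            return self.incidence[(subgroup, arm, event)]
        except KeyError:
            from .exceptions import MissingInputError

            raise MissingInputError(
                f"no safety input for ({subgroup.value}, {arm}, {event})"
            ) from None

    def events(self, subgroup: Subgroup, arm: str) -> List[str]:
        return sorted(e for (sg, a, e) in self.incidence if sg == subgroup and a == arm)


class InputDeck(NamedTuple):
    clinical: ClinicalInputTable
    costs: CountryCostTable
    resource_use: ResourceUseSchedule
    safety: SafetyInputTable


def _kfmt(key) -> str:
    return "(" + ", ".join(getattr(k, "value", str(k)) for k in key) + ")"


# --------------------------------------------------------------------------
# scalar operations
# --------------------------------------------------------------------------


def price_per_mg(unit_price: float, unit_size_mg: float) -> float:
    """Price per milligram at full precision.

    Display values (matching a printed per-mg column) are obtained with
    :func:`rheumcca._util.round_half_up` at 2 decimals; internal computations
    never round.
    """
    if unit_size_mg <= 0:
        raise DomainError(f"unit_size_mg must be > 0, got {unit_size_mg}")
    if unit_price < 0:
        raise DomainError(f"unit_price must be >= 0, got {unit_price}")
    return unit_price / unit_size_mg


def display_price_per_mg(unit_price: float, unit_size_mg: float, ndigits: int = 2) -> float:
    """Per-mg price rounded half-up for display, as in a printed price column."""
    return round_half_up(price_per_mg(unit_price, unit_size_mg), ndigits)


def assign_subgroup(titre: float) -> Tuple[Subgroup, Optional[Subgroup]]:
    """Map an ACPA titre (AU/mL) to (serostatus, quartile).

    Titres below 25 are ACPA-negative (quartile ``None``).  Positive titres
    get the quartile whose closed interval contains them; titres in the
    printed inter-quartile gaps are assigned to the nearest interval by
    distance, ties to the lower quartile.
    """
    if titre < 0:
        raise DomainError(f"titre must be >= 0, got {titre}")
    if titre < 25.0:
        return Subgroup.ACPA_NEG, None
    best = None
    best_dist = math.inf
    for q in QUARTILES:
        lo, hi = TITRE_RANGES[q]
        dist = max(lo - titre, titre - hi, 0.0)
        if dist < best_dist - 1e-12:  # strict improvement; ties keep lower quartile
            best, best_dist = q, dist
    return Subgroup.ACPA_POS, best


# --------------------------------------------------------------------------
# fixtures
# --------------------------------------------------------------------------


def table1_fixture() -> ClinicalInputTable:
    """Clinical inputs as printed: 64 percentages over 8 outcomes x 8 columns.

    Covers the ACPA-negative, ACPA-positive, Q1 and Q4 subgroups with arm
    sizes 66/54, 185/203, 42/55 and 46/51 (abatacept/adalimumab).  The middle
    quartiles Q2/Q3 were not printed and are absent.
    """
    proportions = {}
    for measure_label, row in _tables.CLINICAL_PERCENT.items():
        measure = OutcomeMeasure(measure_label)
        for (sg_label, arm), pct in zip(_tables.CLINICAL_COLUMNS, row):
            proportions[(Subgroup(sg_label), arm, measure)] = pct / 100.0
    arm_n = {(Subgroup(sg), arm): n for (sg, arm), n in _tables.ARM_N.items()}
    return ClinicalInputTable(proportions=proportions, arm_n=arm_n)


_SCHEDULES = {
    "abatacept": DoseSchedule(dose_mg=125.0, interval_weeks=1.0, route="subcutaneous"),
    "adalimumab": DoseSchedule(dose_mg=40.0, interval_weeks=2.0, route="subcutaneous"),
}


def table2_fixture(country: str) -> CountryCostTable:
    """Unit-cost table for one of DE, IT, ES, US, CA.

    Drug pack prices and monitoring unit costs are the printed values;
    adverse-event management tariffs are synthetic package defaults (the
    source costed them from national DRG databases without printing them).
    Drugs absent from a country's printed block (NSAIDs in the US,
    cyclosporine in Spain) are omitted, not imputed.
    """
    if country not in COUNTRIES:
        raise UnsupportedCountryError(f"unsupported country {country!r}; expected one of {COUNTRIES}")
    drugs = {}
    for name, (route, size_mg, price, printed) in _tables.DRUG_COSTS[country].items():
        drugs[name] = DrugCost(
            name=name,
            unit_size_mg=size_mg,
            unit_price=price,
            route=route,
            schedule=_SCHEDULES.get(name),
            printed_price_per_mg=printed,
        )
    return CountryCostTable(
        country=country,
        currency=_tables.CURRENCY[country],
        price_year=_tables.PRICE_YEAR[country],
        drugs=drugs,
        monitoring_unit_costs=dict(_tables.MONITORING_COSTS[country]),
        ae_class_costs=dict(_tables.AE_CLASS_COSTS[country]),
        frequent_ae_costs=dict(_tables.FREQUENT_AE_COSTS[country]),
    )


# --------------------------------------------------------------------------
# deck I/O
# --------------------------------------------------------------------------


def write_input_deck(path, deck: InputDeck) -> None:
    """Write the four component tables of ``deck`` as CSV files under ``path``."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    clin_rows = []
    for (sg, arm, m), p in sorted(
        deck.clinical.proportions.items(),
        key=lambda kv: (kv[0][0].value, kv[0][1], kv[0][2].value),
    ):
        clin_rows.append((sg.value, arm, m.value, round(p * 100.0, 10)))
    for (sg, arm), n in sorted(deck.clinical.arm_n.items(), key=lambda kv: (kv[0][0].value, kv[0][1])):
        clin_rows.append((sg.value, arm, "N", n))
    pd.DataFrame(clin_rows, columns=["subgroup", "arm", "measure", "value"]).to_csv(
        path / "clinical.csv", index=False
    )

    cost_rows = []
    c = deck.costs
    for name, d in sorted(c.drugs.items()):
        s = d.schedule
        cost_rows.append(
            ("drug", name, d.route, d.unit_size_mg, d.unit_price,
             s.dose_mg if s else "", s.interval_weeks if s else "",
             int(s.per_kg) if s else "", d.printed_price_per_mg if d.printed_price_per_mg is not None else "")
        )
    for item, cost in sorted(c.monitoring_unit_costs.items()):
        cost_rows.append(("monitoring", item, "", "", cost, "", "", "", ""))
    for item, cost in sorted(c.ae_class_costs.items()):
        cost_rows.append(("ae_class", item, "", "", cost, "", "", "", ""))
    for item, cost in sorted(c.frequent_ae_costs.items()):
        cost_rows.append(("ae_item", item, "", "", cost, "", "", "", ""))
    df = pd.DataFrame(
        cost_rows,
        columns=["record", "name", "route", "unit_size_mg", "unit_price",
                 "dose_mg", "interval_weeks", "per_kg", "printed_price_per_mg"],
    )
    df.insert(0, "country", c.country)
    df.insert(1, "currency", c.currency)
    df.insert(2, "price_year", c.price_year)
    df.to_csv(path / "costs.csv", index=False)

    r = deck.resource_use
    ru_rows = [
        ("monitoring", "outpatient_visits_per_year", r.outpatient_visits_per_year, "", ""),
        ("monitoring", "radiographs_per_year", r.radiographs_per_year, "", ""),
        ("monitoring", "blood_test_series_per_year", r.blood_test_series_per_year, "", ""),
    ]
    for name, mg_per_day, exposure in r.concomitant_regimen:
        ru_rows.append(("concomitant", name, "", mg_per_day, exposure))
    pd.DataFrame(
        ru_rows, columns=["record", "name", "rate_per_year", "mg_per_day", "exposure"]
    ).to_csv(path / "resource_use.csv", index=False)

    saf_rows = [
        (sg.value, arm, event, inc)
        for (sg, arm, event), inc in sorted(
            deck.safety.incidence.items(), key=lambda kv: (kv[0][0].value, kv[0][1], kv[0][2])
        )
    ]
    pd.DataFrame(saf_rows, columns=["subgroup", "arm", "event", "incidence"]).to_csv(
        path / "safety.csv", index=False
    )


def load_input_deck(path) -> InputDeck:
    """Load and validate a deck directory; see :func:`write_input_deck` for layout.

    Raises :class:`DeckIncompleteError` if any component file is missing and
    :class:`ValidationError` (with file/row coordinates) on invariant breaches.
    """
    path = Path(path)
    missing = [f for f in DECK_FILES if not (path / f).is_file()]
    if missing:
        raise DeckIncompleteError(f"deck at {path} is missing {', '.join(missing)}")

    # clinical
    fname = path / "clinical.csv"
    df = pd.read_csv(fname)
    proportions, arm_n = {}, {}
    for i, row in df.iterrows():
        coord = f"{fname}:{i + 2}"
        try:
            sg = Subgroup(row["subgroup"])
        except ValueError:
            raise ValidationError(f"{coord}: unknown subgroup {row['subgroup']!r}")
        arm = str(row["arm"])
        if row["measure"] == "N":
            arm_n[(sg, arm)] = int(row["value"])
            continue
        try:
            m = OutcomeMeasure(row["measure"])
        except ValueError:
            raise ValidationError(f"{coord}: unknown outcome {row['measure']!r}")
        pct = float(row["value"])
        if not 0.0 <= pct <= 100.0:
            raise ValidationError(f"{coord}: percentage out of [0,100]: {pct}")
        proportions[(sg, arm, m)] = pct / 100.0
    try:
        clinical = ClinicalInputTable(proportions=proportions, arm_n=arm_n)
    except ValidationError as e:
        raise ValidationError(f"{fname}: {e}") from None

    # costs
    fname = path / "costs.csv"
    df = pd.read_csv(fname)
    if df.empty:
        raise ValidationError(f"{fname}: empty cost table")
    country = str(df["country"].iloc[0])
    currency = str(df["currency"].iloc[0])
    price_year = int(df["price_year"].iloc[0])
    drugs, monitoring, ae_class, ae_item = {}, {}, {}, {}
    for i, row in df.iterrows():
        coord = f"{fname}:{i + 2}"
        rec, name = row["record"], str(row["name"])
        try:
            if rec == "drug":
                schedule = None
                if not pd.isna(row["dose_mg"]) and str(row["dose_mg"]) != "":
                    schedule = DoseSchedule(
                        dose_mg=float(row["dose_mg"]),
                        interval_weeks=float(row["interval_weeks"]),
                        route=str(row["route"]),
                        per_kg=bool(int(row["per_kg"])),
                    )
                printed = None
                if "printed_price_per_mg" in row and not pd.isna(row["printed_price_per_mg"]):
                    printed = float(row["printed_price_per_mg"])
                drugs[name] = DrugCost(
                    name=name,
                    unit_size_mg=float(row["unit_size_mg"]),
                    unit_price=float(row["unit_price"]),
                    route=str(row["route"]),
                    schedule=schedule,
                    printed_price_per_mg=printed,
                )
            elif rec == "monitoring":
                monitoring[name] = float(row["unit_price"])
            elif rec == "ae_class":
                ae_class[name] = float(row["unit_price"])
            elif rec == "ae_item":
                ae_item[name] = float(row["unit_price"])
            else:
                raise ValidationError(f"unknown record type {rec!r}")
        except (ValidationError, ValueError) as e:
            raise ValidationError(f"{coord}: {e}") from None
    try:
        costs = CountryCostTable(
            country=country,
            currency=currency,
            price_year=price_year,
            drugs=drugs,
            monitoring_unit_costs=monitoring,
            ae_class_costs=ae_class,
            frequent_ae_costs=ae_item,
        )
    except ValidationError as e:
        raise ValidationError(f"{fname}: {e}") from None

    # resource use
    fname = path / "resource_use.csv"
    df = pd.read_csv(fname)
    rates = {}
    regimen = []
    for i, row in df.iterrows():
        coord = f"{fname}:{i + 2}"
        if row["record"] == "monitoring":
            rates[str(row["name"])] = float(row["rate_per_year"])
        elif row["record"] == "concomitant":
            regimen.append((str(row["name"]), float(row["mg_per_day"]), float(row["exposure"])))
        else:
            raise ValidationError(f"{coord}: unknown record type {row['record']!r}")
    try:
        resource_use = ResourceUseSchedule(
            outpatient_visits_per_year=rates.get("outpatient_visits_per_year", 0.0),
            radiographs_per_year=rates.get("radiographs_per_year", 0.0),
            blood_test_series_per_year=rates.get("blood_test_series_per_year", 0.0),
            concomitant_regimen=tuple(regimen),
        )
    except ValidationError as e:
        raise ValidationError(f"{fname}: {e}") from None

    # safety
    fname = path / "safety.csv"
    df = pd.read_csv(fname)
    incidence = {}
    for i, row in df.iterrows():
        coord = f"{fname}:{i + 2}"
        try:
            sg = Subgroup(row["subgroup"])
        except ValueError:
            raise ValidationError(f"{coord}: unknown subgroup {row['subgroup']!r}")
        inc = float(row["incidence"])
        if not 0.0 <= inc <= 1.0:
            raise ValidationError(f"{coord}: incidence out of [0,1]: {inc}")
        incidence[(sg, str(row["arm"]), str(row["event"]))] = inc
    try:
        safety = SafetyInputTable(incidence=incidence)
    except ValidationError as e:
        raise ValidationError(f"{fname}: {e}") from None

    return InputDeck(clinical=clinical, costs=costs, resource_use=resource_use, safety=safety)


__all__ = [
    "ARMS",
    "COUNTRIES",
    "Subgroup",
    "TITRE_RANGES",
    "QUARTILES",
    "OutcomeMeasure",
    "RESPONSE_MEASURES",
    "REMISSION_MEASURES",
    "SAFETY_CLASSES",
    "DISCONTINUATION_CLASSES",
    "ClinicalInputTable",
    "DoseSchedule",
    "DrugCost",
    "CountryCostTable",
    "ResourceUseSchedule",
    "SafetyInputTable",
    "InputDeck",
    "price_per_mg",
    "display_price_per_mg",
    "assign_subgroup",
    "table1_fixture",
    "table2_fixture",
    "load_input_deck",
    "write_input_deck",
]
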