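"""Cost engine: dosing, acquisition, concomitant, monitoring, AE management."""

import dataclasses

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rheumcca import Subgroup, expected_counts
from rheumcca.cost_engine import (
    CostBreakdown,
    ae_management_cost,
    arm_total_cost,
    concomitant_cost,
    doses_in_horizon,
    drug_acquisition_cost,
    monitoring_cost,
)
from rheumcca.exceptions import DomainError, MissingPriceError
from rheumcca.inputs_io import (
    CountryCostTable,
    DoseSchedule,
    DrugCost,
    OutcomeMeasure,
    ResourceUseSchedule,
    table2_fixture,
)

WEEKLY = DoseSchedule(dose_mg=125.0, interval_weeks=1.0)
BIWEEKLY = DoseSchedule(dose_mg=40.0, interval_weeks=2.0)


class TestDosesInHorizon:
    @pytest.mark.parametrize(
        "schedule, horizon, expected",
        [(WEEKLY, 104, 104), (BIWEEKLY, 104, 52), (WEEKLY, 0, 0), (BIWEEKLY, 103, 51)],
    )
    def test_examples(self, schedule, horizon, expected):
        assert doses_in_horizon(schedule, horizon) == expected

    def test_negative_horizon_rejected(self):
        with pytest.raises(DomainError):
            doses_in_horizon(WEEKLY, -1)


class TestDrugAcquisition:
    def test_de_biologics_over_two_years(self, de_costs):
        aba = drug_acquisition_cost(de_costs.drug("abatacept"), 104)
        ada = drug_acquisition_cost(de_costs.drug("adalimumab"), 104)
        assert aba == pytest.approx(104 * 346.16)  # 36,000.64
        assert ada == pytest.approx(52 * 871.89)  # 45,338.28

    def test_weight_based_dosing_ceils_to_whole_units(self):
        drug = DrugCost(
            name="x", unit_size_mg=100.0, unit_price=10.0,
            schedule=DoseSchedule(dose_mg=10.0, interval_weeks=4.0, per_kg=True),
        )
        # 10 mg/kg x 80.5 kg = 805 mg -> 9 whole 100 mg units, 26 doses
        assert drug_acquisition_cost(drug, 104, weight_kg=80.5) == 26 * 9 * 10.0

    def test_zero_price_drug(self):
        drug = DrugCost(name="x", unit_size_mg=125.0, unit_price=0.0, schedule=WEEKLY)
        assert drug_acquisition_cost(drug, 104) == 0.0

    def test_unscheduled_drug_rejected(self, de_costs):
        with pytest.raises(DomainError):
            drug_acquisition_cost(de_costs.drug("methotrexate"), 104)


class TestConcomitantCost:
    def _costs_with_per_mg(self, per_mg=0.52):
        drug = DrugCost(name="methotrexate", unit_size_mg=2.5, unit_price=per_mg * 2.5)
        return CountryCostTable(
            country="DE", currency="EUR", price_year=2016,
            drugs={"methotrexate": drug},
            monitoring_unit_costs={}, ae_class_costs={},
        )

    def test_weekly_mtx_example(self):
        # 20 mg/week at 0.52/mg over 104 weeks, full exposure -> 1081.60
        use = ResourceUseSchedule(0, 0, 0, (("methotrexate", 20.0 / 7.0, 1.0),))
        cost = concomitant_cost(use, self._costs_with_per_mg(0.52), 104)
        assert cost == pytest.approx(20 * 104 * 0.52)

    def test_exposure_scales_linearly(self):
        full = ResourceUseSchedule(0, 0, 0, (("methotrexate", 20.0 / 7.0, 1.0),))
        half = ResourceUseSchedule(0, 0, 0, (("methotrexate", 20.0 / 7.0, 0.5),))
        costs = self._costs_with_per_mg()
        assert concomitant_cost(half, costs, 104) == pytest.approx(
            concomitant_cost(full, costs, 104) / 2
        )

    def test_empty_regimen_is_free(self):
        use = ResourceUseSchedule(0, 0, 0, ())
        assert concomitant_cost(use, self._costs_with_per_mg(), 104) == 0.0

    def test_unpriced_drug_error_names_the_drug(self):
        use = ResourceUseSchedule(0, 0, 0, (("leflunomide", 20.0, 1.0),))
        with pytest.raises(MissingPriceError, match="leflunomide"):
            concomitant_cost(use, self._costs_with_per_mg(), 104)


class TestMonitoringCost:
    def test_de_outpatient_visits_example(self, de_costs):
        use = ResourceUseSchedule(4.0, 0.0, 0.0, ())
        assert monitoring_cost(use, de_costs, 104) == pytest.approx(4 * 2 * 62.60)

    def test_zero_rates(self, de_costs):
        use = ResourceUseSchedule(0.0, 0.0, 0.0, ())
        assert monitoring_cost(use, de_costs, 104) == 0.0

    def test_linear_in_horizon(self, de_costs, de_resource_use):
        assert monitoring_cost(de_resource_use, de_costs, 208) == pytest.approx(
            2 * monitoring_cost(de_resource_use, de_costs, 104)
        )


class TestAEManagementCost:
    def test_counts_times_tariffs(self, clinical, safety, de_costs):
        out = expected_counts(clinical, safety, Subgroup.ACPA_NEG, "adalimumab", 1000)
        assert out.safety_events["SAE"] == 93
        cost = ae_management_cost(out, de_costs)
        manual = sum(
            c * (de_costs.ae_class_costs.get(e) or de_costs.frequent_ae_costs[e])
            for e, c in out.safety_events.items()
        )
        assert cost == pytest.approx(manual)

    def test_zero_events_cost_nothing(self, clinical, de_costs, safety):
        out = expected_counts(clinical, safety, Subgroup.Q4, "abatacept", 1000)
        zeroed = dataclasses.replace(
            out, safety_events={e: 0 for e in out.safety_events}
        )
        assert ae_management_cost(zeroed, de_costs) == 0.0

    def test_unlisted_ae_priced_at_average_of_listed(self, clinical, safety, de_costs):
        out = expected_counts(clinical, safety, Subgroup.Q4, "abatacept", 1000)
        with_other = dataclasses.replace(out, safety_events={"rash": 10})
        expected = 10 * (
            sum(de_costs.frequent_ae_costs.values()) / len(de_costs.frequent_ae_costs)
        )
        assert ae_management_cost(with_other, de_costs) == pytest.approx(expected)


class TestArmTotalCost:
    def test_additivity_example(self):
        b = CostBreakdown.from_components(
            "abatacept", Subgroup.Q4, "EUR", 1000,
            {"drug_acquisition": 100, "concomitant": 50, "monitoring": 25,
             "ae_management": 10},
        )
        assert b.total == 185.0

    @given(
        st.lists(
            st.floats(min_value=0, max_value=1e8, allow_nan=False),
            min_size=1, max_size=5,
        )
    )
    @settings(max_examples=100, deadline=None)
    def test_total_equals_component_sum_to_the_cent(self, values):
        comps = {f"c{i}": v for i, v in enumerate(values)}
        b = CostBreakdown.from_components("abatacept", Subgroup.Q4, "EUR", 1000, comps)
        assert b.total_cents == sum(b.component_cents.values())

    def test_full_breakdown_and_drug_share(self, clinical, safety, de_costs,
                                           de_resource_use):
        out = expected_counts(clinical, safety, Subgroup.Q1, "abatacept", 1000)
        b = arm_total_cost(out, de_costs, de_resource_use, 104, 80.5)
        assert b.total_cents == sum(b.component_cents.values())
        share = b.components["drug_acquisition"] / b.total
        assert abs(share - 0.9) < 0.10  # acquisition dominates total costs

    def test_homogeneity_in_unit_costs(self, clinical, safety, de_costs,
                                       de_resource_use):
        out = expected_counts(clinical, safety, Subgroup.Q1, "abatacept", 1000)
        base = arm_total_cost(out, de_costs, de_resource_use, 104, 80.5)
        k = 2.0
        scaled_costs = dataclasses.replace(
            de_costs,
            drugs={n: dataclasses.replace(d, unit_price=d.unit_price * k)
                   for n, d in de_costs.drugs.items()},
            monitoring_unit_costs={i: v * k for i, v in de_costs.monitoring_unit_costs.items()},
            ae_class_costs={i: v * k for i, v in de_costs.ae_class_costs.items()},
            frequent_ae_costs={i: v * k for i, v in de_costs.frequent_ae_costs.items()},
        )
        scaled = arm_total_cost(out, scaled_costs, de_resource_use, 104, 80.5)
        assert scaled.total == pytest.approx(k * base.total, abs=0.05)

    def test_monotone_in_any_unit_cost(self, clinical, safety, de_costs,
                                       de_resource_use):
        out = expected_counts(clinical, safety, Subgroup.Q1, "abatacept", 1000)
        base = arm_total_cost(out, de_costs, de_resource_use, 104, 80.5)
        bumped_costs = dataclasses.replace(
            de_costs,
            ae_class_costs={**de_costs.ae_class_costs,
                            "SAE": de_costs.ae_class_costs["SAE"] + 100.0},
        )
        bumped = arm_total_cost(out, bumped_costs, de_resource_use, 104, 80.5)
        assert bumped.total >= base.total

    def test_zero_horizon_leaves_only_ae_management(self, clinical, safety, de_costs,
                                                    de_resource_use):
        out = expected_counts(clinical, safety, Subgroup.Q1, "abatacept", 1000)
        b = arm_total_cost(out, de_costs, de_resource_use, 0, 80.5)
        assert b.components["drug_acquisition"] == 0.0
        assert b.components["concomitant"] == 0.0
        assert b.components["monitoring"] == 0.0
        assert b.components["ae_management"] > 0.0

    def test_prorated_discontinuation_reduces_drug_cost(self, clinical, safety,
                                                        de_costs, de_resource_use):
        out = expected_counts(clinical, safety, Subgroup.Q1, "abatacept", 1000)
        full = arm_total_cost(out, de_costs, de_resource_use, 104, 80.5)
        pro = arm_total_cost(out, de_costs, de_resource_use, 104, 80.5,
                             prorate_discontinuation=True)
        assert pro.components["drug_acquisition"] < full.components["drug_acquisition"]
        assert pro.components["ae_management"] == full.components["ae_management"]
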