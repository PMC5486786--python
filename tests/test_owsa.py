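"""OWSA distribution assignment, moment recovery, tornado behaviour."""

import math

import numpy as np
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st

from rheumcca import Subgroup
from rheumcca.exceptions import BetaInfeasibleError, DomainError, NotVariableError
from rheumcca.owsa import (
    BetaSpec,
    DirectBounds,
    ParameterSpec,
    TriangularSpec,
    assign_distribution,
    beta_from_mean_sd,
    ci_bounds,
    run_owsa,
    triangular_from_mean_sd,
)


class TestBetaFromMeanSD:
    def test_canonical_example(self):
        alpha, beta = beta_from_mean_sd(0.1, 0.1)
        assert alpha == pytest.approx(0.8, abs=1e-12)
        assert beta == pytest.approx(7.2, abs=1e-12)
        # variance check: 0.1 * 0.9 / 9 = 0.01
        spec = BetaSpec(alpha, beta)
        assert spec.sd**2 == pytest.approx(0.01, abs=1e-12)

    @given(
        mean=st.floats(min_value=0.01, max_value=0.99),
        sd_frac=st.floats(min_value=0.05, max_value=0.95),
    )
    @settings(max_examples=200, deadline=None)
    def test_moment_recovery_closed_form(self, mean, sd_frac):
        sd = sd_frac * math.sqrt(mean * (1 - mean))
        alpha, beta = beta_from_mean_sd(mean, sd)
        spec = BetaSpec(alpha, beta)
        assert spec.mean == pytest.approx(mean, abs=1e-9)
        assert spec.sd == pytest.approx(sd, abs=1e-9)

    def test_infeasible_mean_half_with_sd_equal_mean(self):
        with pytest.raises(BetaInfeasibleError) as exc:
            beta_from_mean_sd(0.5, 0.5)
        assert exc.value.clamped_sd == pytest.approx(0.95 * 0.5)

    def test_domain_checks(self):
        with pytest.raises(DomainError):
            beta_from_mean_sd(0.0, 0.1)
        with pytest.raises(DomainError):
            beta_from_mean_sd(0.5, 0.0)


class TestTriangularFromMeanSD:
    def test_canonical_example(self):
        lower, mode, upper = triangular_from_mean_sd(10.0, 3.0)
        assert lower == pytest.approx(2.652, abs=5e-4)
        assert mode == 10.0
        assert upper == pytest.approx(17.348, abs=5e-4)
        assert upper - mode == pytest.approx(3.0 * math.sqrt(6.0), abs=1e-12)

    def test_closed_form_sd_recovered(self):
        spec = TriangularSpec(*triangular_from_mean_sd(10.0, 3.0))
        assert spec.sd == pytest.approx(3.0, abs=1e-9)
        assert spec.mean == pytest.approx(10.0, abs=1e-9)

    def test_zero_sd_degenerates_to_point(self):
        assert triangular_from_mean_sd(10.0, 0.0) == (10.0, 10.0, 10.0)

    def test_truncation_at_zero_preserves_mean(self):
        lower, mode, upper = triangular_from_mean_sd(2.0, 1.5)  # w = 3.67 > mean
        assert lower == 0.0
        spec = TriangularSpec(lower, mode, upper)
        assert spec.mean == pytest.approx(2.0, abs=1e-12)

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(DomainError):
            triangular_from_mean_sd(0.0, 1.0)


class TestAssignDistribution:
    def test_ci_takes_precedence(self):
        p = ParameterSpec(id="x", value=0.3, kind="proportion", ci95=(0.2, 0.4))
        assert assign_distribution(p) == DirectBounds(0.2, 0.4)

    def test_proportion_gets_beta_with_sd_equal_mean(self):
        spec = assign_distribution(ParameterSpec(id="x", value=0.1, kind="proportion"))
        assert isinstance(spec, BetaSpec)
        assert (spec.alpha, spec.beta) == pytest.approx((0.8, 7.2))

    def test_continuous_gets_triangular_30_percent(self):
        spec = assign_distribution(ParameterSpec(id="x", value=10.0, kind="continuous"))
        assert isinstance(spec, TriangularSpec)
        assert spec.sd == pytest.approx(3.0, abs=1e-9)

    def test_infeasible_beta_is_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamping"):
            spec = assign_distribution(
                ParameterSpec(id="x", value=0.6, kind="proportion")
            )
        assert isinstance(spec, BetaSpec)
        assert spec.mean == pytest.approx(0.6, abs=1e-9)
        assert spec.sd == pytest.approx(0.95 * math.sqrt(0.6 * 0.4), abs=1e-9)

    def test_zero_mean_parameter_never_varies(self):
        p = ParameterSpec(id="x", value=0.0, kind="proportion")
        assert not p.varies
        with pytest.raises(NotVariableError):
            assign_distribution(p)

    def test_fixed_parameter_never_varies(self):
        p = ParameterSpec(id="x", value=80.5, kind="fixed")
        assert not p.varies
        with pytest.raises(NotVariableError):
            assign_distribution(p)


class TestCIBounds:
    def test_direct_bounds_pass_through(self):
        assert ci_bounds(DirectBounds(0.2, 0.4)) == (0.2, 0.4)

    def test_beta_percentiles_bracket_the_mean(self):
        low, high = ci_bounds(BetaSpec(0.8, 7.2))
        assert 0.0 < low < 0.1 < high < 1.0

    def test_triangular_bounds_within_support(self):
        spec = TriangularSpec(*triangular_from_mean_sd(10.0, 3.0))
        low, high = ci_bounds(spec)
        assert spec.lower < low < spec.mode < high < spec.upper

    def test_degenerate_triangular(self):
        assert ci_bounds(TriangularSpec(10.0, 10.0, 10.0)) == (10.0, 10.0)


class TestSamplingAgreement:
    @pytest.mark.parametrize(
        "spec, mean, sd",
        [
            (BetaSpec(0.8, 7.2), 0.1, 0.1),
            (TriangularSpec(*triangular_from_mean_sd(10.0, 3.0)), 10.0, 3.0),
        ],
    )
    def test_simulated_moments_match(self, spec, mean, sd):
        rng = np.random.default_rng(12345)
        draws = spec.sample(rng, 100_000)
        se_mean = sd / math.sqrt(100_000)
        assert abs(draws.mean() - mean) < 3 * se_mean
        assert abs(draws.std() - sd) < 0.02 * sd + 3 * se_mean


class TestRunOWSA:
    def _linear_runner(self, baseline=-100.0, coef=2.0):
        # incremental cost linear in parameter "a" around value 50
        def runner(overrides):
            a = overrides.get("a", 50.0)
            return baseline + coef * (a - 50.0)

        return runner

    def test_envelope_contains_baseline_for_linear_parameter(self):
        params = [ParameterSpec(id="a", value=50.0, kind="continuous")]
        entries = run_owsa(self._linear_runner(), params)
        assert len(entries) == 1
        e = entries[0]
        assert e.low_result < -100.0 < e.high_result

    def test_fixed_and_zero_parameters_excluded(self):
        params = [
            ParameterSpec(id="a", value=50.0, kind="continuous"),
            ParameterSpec(id="fixed", value=104.0, kind="fixed"),
            ParameterSpec(id="zero", value=0.0, kind="proportion"),
        ]
        entries = run_owsa(self._linear_runner(), params)
        assert [e.parameter for e in entries] == ["a"]

    def test_degenerate_bounds_give_zero_range(self):
        params = [ParameterSpec(id="a", value=50.0, kind="continuous",
                                ci95=(50.0, 50.0))]
        entries = run_owsa(self._linear_runner(), params)
        assert entries[0].range == 0.0
        assert not entries[0].crosses_zero

    def test_failure_at_bound_is_flagged_and_run_continues(self):
        def runner(overrides):
            if "bad" in overrides:
                raise RuntimeError("boom")
            return self._linear_runner()(overrides)

        params = [
            ParameterSpec(id="a", value=50.0, kind="continuous"),
            ParameterSpec(id="bad", value=1.0, kind="continuous"),
        ]
        entries = run_owsa(runner, params)
        flagged = {e.parameter: e for e in entries}
        assert flagged["bad"].failed
        assert not flagged["a"].failed

    def test_entries_sorted_by_descending_range_ties_by_id(self):
        def runner(overrides):
            return sum(overrides.values())

        params = [
            ParameterSpec(id=pid, value=10.0, kind="continuous")
            for pid in ("b", "a", "c")
        ]
        entries = run_owsa(runner, params)
        ranges = [e.range for e in entries]
        assert ranges == sorted(ranges, reverse=True)
        assert [e.parameter for e in entries] == ["a", "b", "c"]  # equal ranges


class TestModelSensitivity:
    def test_abatacept_price_rise_flips_incremental_cost_sign(self, model_factory):
        model = model_factory("DE", Subgroup.Q1)
        baseline = model.incremental_cost_at({})
        assert baseline < 0  # abatacept cost saving at list price
        tornado = model.sensitivity()
        entry = next(e for e in tornado.entries if e.parameter == "price.abatacept")
        assert entry.low_result < baseline < entry.high_result  # monotone increase
        assert entry.high_result > 0  # no longer cost saving at the upper bound
        assert entry.crosses_zero

    @pytest.mark.parametrize("country", ["DE", "ES", "US", "CA"])
    def test_biologic_prices_dominate_tornado(self, model_factory, country):
        model = model_factory(country, Subgroup.ACPA_POS)
        entries = model.sensitivity().entries
        top3 = {e.parameter for e in entries[:3]}
        assert {"price.abatacept", "price.adalimumab"} <= top3
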