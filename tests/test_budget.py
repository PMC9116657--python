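"""Weight-budget MNI model: forward budgets, inverse solver, oracle checks."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ustrina.budget import (
    AgeSexClass,
    BudgetModelError,
    DemographicScenario,
    MNIBudgetModel,
    compare_hypotheses,
    forward_weight,
    generational_deaths,
    per_capita_contribution,
    salorno_hypothesis_a,
    salorno_hypothesis_b,
    salorno_scenarios,
    scenario_from_yaml,
    scenario_to_yaml,
    solve_mni,
)

OBSERVED = 63555.0


class TestPerCapita:
    def test_residual_contributions_from_urn_references(self):
        male = AgeSexClass("adult_male", 2500.0, collected_mass=1695.0)
        female = AgeSexClass("adult_female", 1800.0, collected_mass=1443.0)
        assert per_capita_contribution(male, "residual") == 805.0
        assert per_capita_contribution(female, "residual") == 357.0
        assert per_capita_contribution(male, "primary") == 2500.0

    def test_full_collection_leaves_zero(self):
        cls = AgeSexClass("x", 500.0, collected_mass=500.0)
        assert per_capita_contribution(cls, "residual") == 0.0

    def test_residual_override_takes_precedence(self):
        cls = AgeSexClass("subadult", 500.0, collected_mass=157.0, residual_override=157.0)
        assert per_capita_contribution(cls, "residual") == 157.0

    def test_overcollection_rejected(self):
        cls = AgeSexClass("x", 500.0, collected_mass=600.0)
        with pytest.raises(BudgetModelError):
            per_capita_contribution(cls, "residual")


class TestForwardWeight:
    def test_primary_budget(self):
        # 12 males + 12 females + 24 subadults at full skeleton masses
        assert forward_weight(salorno_hypothesis_a(), (12, 12, 24)) == 63600.0

    def test_residual_budget_with_157g_subadult(self):
        # 43/43/86 at residuals 805/357/157 reproduces the published total
        assert forward_weight(salorno_hypothesis_b("reproduced"), (43, 43, 86)) == 63468.0

    def test_literal_printed_subadult_term_differs(self):
        # the literally printed 500-157=343 g subadult residual does NOT
        # give the published 63,468 g — the documented inconsistency
        w = forward_weight(salorno_hypothesis_b("printed"), (43, 43, 86))
        assert w == 43 * 805 + 43 * 357 + 86 * 343
        assert w != 63468.0

    def test_zero_counts(self):
        assert forward_weight(salorno_hypothesis_a(), (0, 0, 0)) == 0.0

    def test_count_length_mismatch_rejected(self):
        with pytest.raises(BudgetModelError):
            forward_weight(salorno_hypothesis_a(), (1, 2))


class TestSolver:
    def test_primary_scenario_mni(self):
        res = solve_mni(salorno_hypothesis_a(), OBSERVED)
        assert res.unit_count == 12
        assert res.counts == (12, 12, 24)
        assert res.mni == 48
        assert res.modelled_mass == 63600.0
        assert res.misfit == pytest.approx(45.0)

    def test_residual_scenario_mni(self):
        res = solve_mni(salorno_hypothesis_b("reproduced"), OBSERVED)
        assert res.unit_count == 43
        assert res.counts == (43, 43, 86)
        assert res.mni == 172

    def test_nearest_rounding_is_half_up(self):
        # 63,555 / 5,300 = 11.99 -> 12; floor would give 11
        assert solve_mni(salorno_hypothesis_a(), OBSERVED, "floor").unit_count == 11
        assert solve_mni(salorno_hypothesis_a(), OBSERVED, "ceil").unit_count == 12
        scenario = DemographicScenario((AgeSexClass("a", 100.0),))
        assert solve_mni(scenario, 150.0, "nearest").unit_count == 2  # half rounds up

    def test_zero_observed(self):
        res = solve_mni(salorno_hypothesis_a(), 0.0)
        assert res.unit_count == res.mni == 0

    def test_zero_unit_contribution_rejected(self):
        scenario = DemographicScenario((AgeSexClass("x", 0.0),))
        with pytest.raises(BudgetModelError):
            solve_mni(scenario, 100.0)

    def test_solver_matches_brute_force_oracle(self):
        """Nearest-rounding solution equals exhaustive misfit minimisation."""
        rng = np.random.default_rng(12345)
        for _ in range(1000):
            n_classes = rng.integers(1, 4)
            classes = tuple(
                AgeSexClass(f"c{i}", float(rng.uniform(100, 3000)),
                            ratio=int(rng.integers(1, 4)))
                for i in range(n_classes)
            )
            scenario = DemographicScenario(classes)
            observed = float(rng.uniform(0, 5e5))
            res = solve_mni(scenario, observed)
            units = np.arange(0, 10001)
            misfit = np.abs(units * scenario.unit_contribution - observed)
            assert res.unit_count == int(units[np.argmin(misfit)])

    @settings(max_examples=100, deadline=None)
    @given(
        n=st.integers(0, 10000),
        masses=st.lists(st.integers(1, 5000), min_size=1, max_size=4),
    )
    def test_inverse_consistency(self, n, masses):
        """solve_mni(forward_weight(n units)) recovers n exactly."""
        scenario = DemographicScenario(
            tuple(AgeSexClass(f"c{i}", float(m)) for i, m in enumerate(masses))
        )
        w = forward_weight(scenario, [n] * len(masses))
        assert solve_mni(scenario, w).unit_count == n

    def test_mni_monotone_in_observed_total(self):
        scenario = salorno_hypothesis_a()
        mnis = [solve_mni(scenario, w).mni for w in np.linspace(0, 1e5, 200)]
        assert all(b >= a for a, b in zip(mnis, mnis[1:]))

    @given(k=st.integers(-10, 10), w=st.floats(0, 1e5, allow_nan=False))
    def test_homogeneity(self, k, w):
        """Scaling contributions and observed mass together preserves the count.

        Power-of-two scale factors keep the float arithmetic exact, so the
        mathematical identity can be asserted without tolerance.
        """
        c = 2.0**k
        base = DemographicScenario((
            AgeSexClass("a", 2500.0), AgeSexClass("b", 1800.0, ratio=2),
        ))
        scaled = DemographicScenario((
            AgeSexClass("a", 2500.0 * c), AgeSexClass("b", 1800.0 * c, ratio=2),
        ))
        assert solve_mni(base, w).unit_count == solve_mni(scaled, w * c).unit_count


class TestModelResultsShape:
    def test_model_fit_and_predict(self):
        model = MNIBudgetModel(OBSERVED, salorno_hypothesis_a())
        res = model.fit()
        assert res.mni == 48
        assert model.predict(12) == 63600.0

    def test_from_deposit(self, small_deposit):
        model = MNIBudgetModel.from_deposit(small_deposit, salorno_hypothesis_a())
        assert model.observed_total == pytest.approx(968.0)

    def test_summary_reports_key_quantities(self):
        text = MNIBudgetModel(OBSERVED, salorno_hypothesis_a()).fit().summary()
        assert "MNI: 48" in text
        assert "adult_male" in text and "2,500" in text


class TestScenarios:
    def test_ratios_reduce_to_smallest_integers(self):
        scenario = DemographicScenario((
            AgeSexClass("a", 100.0, ratio=2),
            AgeSexClass("b", 100.0, ratio=4),
        ))
        assert scenario.ratios == (1, 2)

    def test_duplicate_class_names_rejected(self):
        with pytest.raises(BudgetModelError):
            DemographicScenario((AgeSexClass("a", 1.0), AgeSexClass("a", 2.0)))

    def test_compare_hypotheses_is_order_equivariant(self):
        scenarios = salorno_scenarios()
        fwd = compare_hypotheses(OBSERVED, scenarios)
        rev = compare_hypotheses(OBSERVED, scenarios[::-1])
        assert [r.mni for r in fwd] == [r.mni for r in rev][::-1]
        assert [r.mni for r in fwd[:2]] == [48, 172]

    def test_single_scenario_report(self):
        assert len(compare_hypotheses(OBSERVED, [salorno_hypothesis_a()])) == 1

    def test_yaml_round_trip(self, tmp_path):
        for scenario in salorno_scenarios():
            path = tmp_path / "s.yaml"
            scenario_to_yaml(scenario, path)
            assert scenario_from_yaml(path) == scenario

    def test_shipped_configs_match_code_constructors(self):
        from importlib import resources

        cfg = resources.files("ustrina") / "configs"
        assert scenario_from_yaml(cfg / "salorno_scenario_a.yaml") == salorno_hypothesis_a()
        assert scenario_from_yaml(
            cfg / "salorno_scenario_b_reproduced.yaml"
        ) == salorno_hypothesis_b("reproduced")
        assert scenario_from_yaml(
            cfg / "salorno_scenario_b_printed.yaml"
        ) == salorno_hypothesis_b("printed")


class TestGenerationalModel:
    def test_two_century_span(self):
        g = generational_deaths(200, 25, 6)
        assert g.generations == 8
        assert g.expected_deaths == 48

    def test_arithmetic(self):
        g = generational_deaths(100, 25, 4)
        assert (g.generations, g.expected_deaths) == (4, 16)

    @pytest.mark.parametrize("args", [(0, 25, 6), (200, 0, 6), (200, 25, 0)])
    def test_nonpositive_inputs_rejected(self, args):
        with pytest.raises(BudgetModelError):
            generational_deaths(*args)
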