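import numpy as np
import pytest

from chestpain_cea.cohort import generate_cohort, hospital_spec
from chestpain_cea.costing import (cost_from_records, drg_mean_cost,
                                   expected_ambulance_cost,
                                   incremental_cost, primary_addon_cost,
                                   strategy_total_cost)
from chestpain_cea.params import load_parameters, resolve_scenario
from chestpain_cea._rounding import round_eur


class TestAmbulanceCost:
    @pytest.mark.parametrize("p,unit,rounded", [
        (0.29, 559, 162),
        (0.0, 559, 0),
        (0.75, 559, 419),
        (0.90, 559, 503),
    ])
    def test_expected_cost(self, p, unit, rounded):
        assert round_eur(expected_ambulance_cost(p, unit)) == rounded

    def test_probability_out_of_range(self):
        with pytest.raises(ValueError):
            expected_ambulance_cost(1.1, 559)


class TestAddonCost:
    def test_base_case_is_192(self, params, base_case):
        assert primary_addon_cost(base_case, params)["total"] == 192

    def test_conservative_is_230(self, params, conservative):
        assert primary_addon_cost(conservative, params)["total"] == 230

    def test_all_components_zeroed(self):
        p = load_parameters({"costs": {"algorithm_lab_cost": 0,
                                       "personnel_cost_wage": 0,
                                       "outpatient_referral_cost": 0}})
        s = resolve_scenario(p, "base_case")
        assert primary_addon_cost(s, p)["total"] == 0


class TestDrgMeanCost:
    @pytest.mark.parametrize("total,n,expected", [
        (840_664, 567, 1483),
        (1000, 1, 1000),
        (840_664, 100, 8407),
    ])
    def test_mean(self, total, n, expected):
        assert round_eur(drg_mean_cost(total, n)) == expected

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            drg_mean_cost(840_664, 0)


class TestStrategyTotals:
    @pytest.mark.parametrize("scenario,strategy,total", [
        ("base_case", "primary_care_algorithm", 520),
        ("base_case", "hospital_standard", 2314),
        ("conservative", "primary_care_algorithm", 558),
        ("conservative", "hospital_standard", 2230),
    ])
    def test_published_totals(self, params, scenario, strategy, total):
        s = resolve_scenario(params, scenario)
        assert strategy_total_cost(s, strategy, params).total == total

    def test_hospital_with_no_ambulance(self, params):
        p = load_parameters({"costs": {"p_ambulance_to_hospital_base": 0.0}})
        s = resolve_scenario(p, "base_case")
        assert strategy_total_cost(s, "hospital_standard", p).total == \
            162 + 166 + 0 + 1483

    def test_unknown_strategy(self, params, base_case):
        with pytest.raises(ValueError):
            strategy_total_cost(base_case, "helicopter", params)

    def test_component_additivity(self, params):
        for scenario in ("base_case", "conservative"):
            s = resolve_scenario(params, scenario)
            for strategy in ("primary_care_algorithm", "hospital_standard"):
                sc = strategy_total_cost(s, strategy, params)
                assert sc.total == sum(c.expected_cost_eur
                                       for c in sc.components)

    @pytest.mark.parametrize("field,delta", [
        ("ems_cost_per_transport", 100),
        ("consultation_cost", 50),
        ("drg_total", 100_000),
        ("p_ambulance_to_hospital_base", 0.05),
    ])
    def test_monotone_in_unit_costs_and_probabilities(self, field, delta):
        lo = load_parameters()
        hi = load_parameters({"costs": {
            field: getattr(lo.costs, field) + delta}})
        for strategy in ("primary_care_algorithm", "hospital_standard"):
            t_lo = strategy_total_cost(resolve_scenario(lo, "base_case"),
                                       strategy, lo).total
            t_hi = strategy_total_cost(resolve_scenario(hi, "base_case"),
                                       strategy, hi).total
            assert t_hi >= t_lo

    def test_shared_components_cancel_in_incremental(self):
        """Perturbing a shared component leaves the cost difference alone."""
        for consult in (0.0, 166.0, 500.0):
            p = load_parameters({"costs": {"consultation_cost": consult}})
            s = resolve_scenario(p, "base_case")
            prim = strategy_total_cost(s, "primary_care_algorithm", p)
            hosp = strategy_total_cost(s, "hospital_standard", p)
            assert incremental_cost(prim, hosp) == -1794


TARIFFS = {"ems_transport": 559.0, "consultation": 166.0,
           "algorithm_addon": 192.0}


class TestCostFromRecords:
    def test_single_hospital_record(self):
        import pandas as pd
        rec = pd.DataFrame([{"setting": "hospital", "los_hours": 20.0,
                             "cost_eur": 1483.0, "ambulance": False}])
        out = cost_from_records(rec, TARIFFS)
        assert out.mean_cost == pytest.approx(1483 + 166)

    def test_empty_records_sentinel(self):
        import pandas as pd
        out = cost_from_records(pd.DataFrame(columns=["setting", "los_hours"]),
                                TARIFFS)
        assert out.empty and out.mean_cost is None

    def test_unknown_tariff_key_named(self):
        import pandas as pd
        rec = pd.DataFrame([{"setting": "hospital", "los_hours": 1.0,
                             "cost_eur": 1.0}])
        with pytest.raises(KeyError, match="consultation"):
            cost_from_records(rec, {"ems_transport": 559.0,
                                    "algorithm_addon": 192.0})

    def test_bottom_up_matches_analytic_tree(self, params):
        """Monte-Carlo record costing converges to the decision-tree total."""
        spec = hospital_spec(n=50_000, seed=3, p_ambulance=0.90)
        records = generate_cohort(spec)
        out = cost_from_records(records, TARIFFS)
        s = resolve_scenario(params, "base_case")
        tree = strategy_total_cost(s, "hospital_standard", params)
        analytic = (0.90 * 559 + 166
                    + tree.component("hospital_drg").unit_cost)
        assert abs(out.mean_cost - analytic) < 3 * out.se
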