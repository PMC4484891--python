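"""Incremental analysis, dominance, OWSA and PSA machinery."""

import numpy as np
import pandas as pd
import pytest

from racua.cea import (Dominance, PSAResult, StrategyResult, ceac,
                       classify_dominance, default_wtp_grid, evaluate_strategy,
                       incremental_analysis, run_owsa, run_psa, sample_psa_draw)
from racua.config import resolve_scenario


class TestClassifyDominance:
    @pytest.mark.parametrize("dc, dq, expected", [
        (-23770, 0.148, Dominance.reference_dominant),
        (1823, 0.148, Dominance.icer_defined),
        (5, -0.1, Dominance.comparator_dominant),
        (-100, -0.1, Dominance.icer_defined),
        (0, 0, Dominance.equal),
        (0, 0.1, Dominance.reference_dominant),
        (-5, 0, Dominance.reference_dominant),
        (5, 0, Dominance.comparator_dominant),
        (0, -0.1, Dominance.comparator_dominant),
    ])
    def test_quadrants(self, dc, dq, expected):
        assert classify_dominance(dc, dq) is expected


class TestIncrementalAnalysis:
    def test_icer_equals_ratio_to_machine_precision(self):
        ref = StrategyResult("A", 140971.0, 6.578)
        comp = StrategyResult("B", 139148.0, 6.430)
        inc = incremental_analysis(ref, comp)
        assert inc.icer == (ref.cost - comp.cost) / (ref.qalys - comp.qalys)

    def test_dominant_pair_has_no_icer(self):
        inc = incremental_analysis(StrategyResult("A", 140971.0, 6.578),
                                   StrategyResult("B", 164741.0, 6.430))
        assert inc.dominance is Dominance.reference_dominant
        assert inc.icer is None

    def test_equal_results(self):
        r = StrategyResult("A", 100.0, 5.0)
        inc = incremental_analysis(r, StrategyResult("B", 100.0, 5.0))
        assert (inc.delta_cost, inc.delta_qaly, inc.dominance) == \
            (0.0, 0.0, Dominance.equal)

    def test_antisymmetry(self):
        a = StrategyResult("A", 140971.0, 6.578)
        b = StrategyResult("B", 139148.0, 6.430)
        fwd = incremental_analysis(a, b)
        rev = incremental_analysis(b, a)
        assert rev.delta_cost == -fwd.delta_cost
        assert rev.delta_qaly == -fwd.delta_qaly
        assert fwd.dominance is Dominance.icer_defined
        assert rev.dominance is Dominance.icer_defined
        assert rev.icer == pytest.approx(fwd.icer)
        mirror = {Dominance.reference_dominant: Dominance.comparator_dominant,
                  Dominance.comparator_dominant: Dominance.reference_dominant}
        f2 = incremental_analysis(a, StrategyResult("C", 164741.0, 6.430))
        r2 = incremental_analysis(StrategyResult("C", 164741.0, 6.430), a)
        assert r2.dominance is mirror[f2.dominance]


class TestEvaluateStrategy:
    def test_cost_linearity_in_unit_prices(self, config, life_table):
        base = evaluate_strategy(config, "CZP+MTX", life_table)
        for duc in config.costs.drug_unit_costs.values():
            duc.cost *= 2
        config.costs.iv_administration_cost *= 2
        for k in config.costs.monitoring_item_costs:
            config.costs.monitoring_item_costs[k] *= 2
        config.costs.haq_band_costs = [2 * c for c in config.costs.haq_band_costs]
        doubled = evaluate_strategy(config, "CZP+MTX", life_table)
        assert doubled.cost == pytest.approx(2 * base.cost, rel=1e-12)
        assert doubled.qalys == pytest.approx(base.qalys, rel=1e-12)

    def test_zero_costs_zero_gains(self, config, life_table):
        for duc in config.costs.drug_unit_costs.values():
            duc.cost = 0.0
        config.costs.iv_administration_cost = 0.0
        config.costs.monitoring_item_costs = {
            k: 0.0 for k in config.costs.monitoring_item_costs}
        config.costs.haq_band_costs = [0.0] * 6
        config.haq_change_by_acr_category = {
            "none": 0.0, "acr20": 0.0, "acr50": 0.0, "acr70": 0.0}
        config.utilities.continuation_gain_fraction = 0.0
        config.utilities.haq_progression_conventional = 0.0
        config.utilities.haq_progression_palliative = 0.0
        res = evaluate_strategy(config, "CZP+MTX", life_table)
        assert res.cost == 0.0
        # utility pinned at baseline: QALYs = 0.38 x discounted person-time
        from racua.engine import run_cohort
        from racua.utility import discounted_qalys
        trace = run_cohort(config, config.strategy("CZP+MTX"), life_table)
        person_time = discounted_qalys(
            (trace.utility > 0).astype(float), trace.occupancy,
            trace.cycle_start_years, trace.cycle_length_years, 0.035)
        assert res.qalys == pytest.approx(0.38 * person_time, rel=1e-9)

    def test_all_strategies_identical_with_zero_gains(self, config, life_table):
        config.haq_change_by_acr_category = {
            "none": 0.0, "acr20": 0.0, "acr50": 0.0, "acr70": 0.0}
        config.utilities.continuation_gain_fraction = 0.0
        config.utilities.haq_progression_conventional = 0.0
        config.utilities.haq_progression_palliative = 0.0
        qalys = {s.name: evaluate_strategy(config, s, life_table).qalys
                 for s in config.strategies}
        vals = list(qalys.values())
        assert all(v == pytest.approx(vals[0], rel=1e-12) for v in vals)

    def test_dominating_response_yields_more_qalys(self, config, life_table):
        # same strategy, component-wise larger cumulative response row
        weak = evaluate_strategy(config, "CZP+MTX", life_table)
        row = config.response["CZP+MTX"].m6
        row.acr20, row.acr50, row.acr70 = 0.85, 0.60, 0.40
        strong = evaluate_strategy(config, "CZP+MTX", life_table)
        assert strong.qalys >= weak.qalys

    def test_per_unit_geq_per_mg(self, base_config, life_table):
        per_mg = resolve_scenario(base_config, "per_mg_costing")
        for s in base_config.strategies:
            a = evaluate_strategy(base_config, s.name, life_table)
            b = evaluate_strategy(per_mg, s.name, life_table)
            assert a.cost >= b.cost - 1e-9
            assert a.qalys == pytest.approx(b.qalys, rel=1e-12)

    def test_qalys_bounded_by_horizon(self, base_config, life_table):
        res = evaluate_strategy(base_config, "CZP+MTX", life_table)
        assert 0 < res.qalys <= base_config.settings.horizon_years
        assert res.cost > 0


class TestOwsa:
    def test_scenario_isolation(self, base_config):
        cfg = resolve_scenario(base_config, "mortality_off")
        assert cfg.mortality.enabled is False
        assert cfg.model_dump(exclude={"mortality"}) == \
            base_config.model_dump(exclude={"mortality"})

    def test_three_month_scenario_uses_3mo_columns(self, base_config, life_table):
        cfg = resolve_scenario(base_config, "acr_3mo")
        base = evaluate_strategy(base_config, "CZP+MTX", life_table)
        alt = evaluate_strategy(cfg, "CZP+MTX", life_table)
        assert alt.qalys != pytest.approx(base.qalys, rel=1e-6)

    def test_iv_admin_scenarios_leave_subcutaneous_unchanged(self, base_config,
                                                             life_table):
        for scen in ("iv_admin_plus20", "iv_admin_minus20"):
            cfg = resolve_scenario(base_config, scen)
            for name in ("CZP+MTX", "ETA", "ADA (weekly)"):
                assert evaluate_strategy(cfg, name, life_table).cost == \
                    pytest.approx(evaluate_strategy(base_config, name,
                                                    life_table).cost, rel=1e-12)
            ifx_base = evaluate_strategy(base_config, "IFX (3 mg/kg)+MTX", life_table)
            ifx_alt = evaluate_strategy(cfg, "IFX (3 mg/kg)+MTX", life_table)
            assert ifx_alt.cost != pytest.approx(ifx_base.cost, rel=1e-9)

    def test_owsa_table_shape(self, base_config, life_table):
        df = run_owsa(base_config, ["horizon_5y"],
                      strategies=["ETA+MTX", "IFX (5 mg/kg)+MTX"],
                      life_table=life_table)
        assert set(df.scenario) == {"base_case", "horizon_5y"}
        assert len(df) == 4
        with pytest.raises(KeyError):
            run_owsa(base_config, ["bogus"], strategies=["ETA+MTX"],
                     life_table=life_table)


class TestPSA:
    def test_draw_determinism(self, base_config):
        a = sample_psa_draw(base_config, np.random.default_rng(5))
        b = sample_psa_draw(base_config, np.random.default_rng(5))
        assert a == b
        c = sample_psa_draw(base_config, np.random.default_rng(6))
        assert a != c

    def test_draw_fractions_in_unit_interval(self, base_config):
        rng = np.random.default_rng(0)
        for _ in range(20):
            d = sample_psa_draw(base_config, rng)
            for trio in d.response.values():
                assert all(0 < p < 1 for p in trio)
            assert d.mortality_rr > 0
            assert 0 < d.proportion_female < 1
            assert d.weight_kg > 0

    def test_lognormal_rr_scale_parameter(self):
        from racua.cea import _lognormal_rr_params
        mu, sigma = _lognormal_rr_params(1.330, (1.099, 1.610))
        assert mu == pytest.approx(np.log(1.330))
        assert sigma == pytest.approx((np.log(1.610) - np.log(1.099)) / 3.92,
                                      rel=1e-3)
        assert sigma == pytest.approx(0.09741, abs=2e-4)

    def test_gender_beta_mean(self, base_config):
        a, b = base_config.psa.gender_beta_shapes
        assert (a, b) == (1506.0, 315.0)
        assert a / (a + b) == pytest.approx(1506 / 1821)

    def test_run_psa_seed_reproducible(self, base_config, life_table):
        kwargs = dict(strategies=["ETA+MTX"], n_draws=3, seed=11,
                      life_table=life_table)
        p1 = run_psa(base_config, **kwargs)
        p2 = run_psa(base_config, **kwargs)
        np.testing.assert_array_equal(p1.delta_cost["ETA+MTX"],
                                      p2.delta_cost["ETA+MTX"])
        np.testing.assert_array_equal(p1.delta_qaly["ETA+MTX"],
                                      p2.delta_qaly["ETA+MTX"])
        p3 = run_psa(base_config, strategies=["ETA+MTX"], n_draws=3, seed=12,
                     life_table=life_table)
        assert (p1.delta_cost["ETA+MTX"] != p3.delta_cost["ETA+MTX"]).any()


class TestCeac:
    def _psa(self, dc, dq):
        dc = np.asarray(dc, float)
        dq = np.asarray(dq, float)
        return PSAResult(seed=0, reference="R", comparators=["C"],
                         delta_cost={"C": dc}, delta_qaly={"C": dq},
                         ref_cost=np.zeros(len(dc)), ref_qalys=np.zeros(len(dc)))

    def test_always_favourable(self):
        curve = ceac(self._psa([-1.0] * 10, [0.1] * 10))
        assert (curve["C"] == 1.0).all()

    def test_never_favourable_at_threshold(self):
        curve = ceac(self._psa([1e6] * 10, [0.001] * 10), np.array([30_000.0]))
        assert curve["C"].iloc[0] == 0.0

    def test_counting_oracle_half(self):
        # half the draws have positive NMB at 30k
        dc = [0.0, 0.0, 40_000.0, 40_000.0]
        dq = [1.0, 1.0, 1.0, 1.0]
        curve = ceac(self._psa(dc, dq), np.array([30_000.0]))
        assert curve["C"].iloc[0] == 0.5

    def test_probability_bounds_and_order_invariance(self):
        rng = np.random.default_rng(3)
        dc = rng.normal(0, 1e4, 50)
        dq = rng.normal(0, 0.2, 50)
        c1 = ceac(self._psa(dc, dq))
        perm = rng.permutation(50)
        c2 = ceac(self._psa(dc[perm], dq[perm]))
        assert ((c1["C"] >= 0) & (c1["C"] <= 1)).all()
        pd.testing.assert_frame_equal(c1, c2)

    def test_grid_includes_threshold(self):
        assert 30_000.0 in default_wtp_grid()

    def test_deterministically_dominant_reference(self, config, life_table):
        # zero-variance proxy: degenerate parameter spread collapses every
        # draw to the base case
        config.psa.response_logodds_se = 1e-12
        for p in ("age", "baseline_haq", "utility_weight", "n_prior_dmards",
                  "disease_duration", "anti_ccp_positive", "anti_ccp_negative"):
            np_param = getattr(config.psa, p)
            np_param.ci = (np_param.mean, np_param.mean)
        config.mortality.rr_ci = (1.330, 1.330)
        config.population.weight_spread_kg = 1e-9
        psa = run_psa(config, strategies=["ADA+MTX (weekly)"], n_draws=4, seed=0,
                      life_table=life_table)
        # gender and weight draws still vary slightly; deltas must stay
        # tightly clustered around the base-case value and dominant
        assert (psa.delta_cost["ADA+MTX (weekly)"] < 0).all()
        assert (psa.delta_qaly["ADA+MTX (weekly)"] > 0).all()
        curve = ceac(psa, np.array([0.0, 30_000.0, 100_000.0]))
        assert (curve["ADA+MTX (weekly)"] == 1.0).all()
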