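"""Cost accrual, ICER computation, net monetary benefit."""

import numpy as np
import pytest

import psmcea
from psmcea.econ import (ArmResult, CEResult, DrugComponent, accrue_costs,
                         compute_icer, cycle_drug_cost, net_monetary_benefit)
from psmcea.engine import ModelSettings, OccupancyTrace


def make_trace(p_pfs, p_pd, settings=None):
    settings = settings or ModelSettings(horizon_years=len(p_pfs) * 42 / 365.25)
    n = len(p_pfs)
    p_pfs, p_pd = np.asarray(p_pfs, float), np.asarray(p_pd, float)
    return OccupancyTrace(settings=settings,
                          time_months=(np.arange(n) + 1) * settings.cycle_months,
                          p_pfs=p_pfs, p_pd=p_pd,
                          p_dead=1.0 - p_pfs - p_pd,
                          discount=np.ones(n))


class TestCycleDrugCost:
    def test_nivolumab_per_mg_arithmetic(self):
        """240 mg q2w, three infusions per 42-day cycle, per-mg from the
        100 mg vial: 3 * 2.4 * 1451.07."""
        nivo = DrugComponent("nivolumab", unit_cost=1451.07,
                             units_per_cycle=7.2, max_duration_months=24.0)
        assert cycle_drug_cost([nivo], 6.0) == pytest.approx(10447.704)

    def test_multiplier_is_linear_for_targets(self):
        nivo = DrugComponent("nivolumab", 1451.07, 9.0, 24.0)
        sun = DrugComponent("sunitinib", 15.37, 28.0)
        full = cycle_drug_cost([nivo, sun], 6.0, 1.0)
        half = cycle_drug_cost([nivo, sun], 6.0, 0.5)
        assert half == pytest.approx(full - 0.5 * nivo.cycle_cost)

    def test_ici_cap_zeroes_cost_after_two_years(self):
        nivo = DrugComponent("nivolumab", 1451.07, 9.0, 24.0)
        assert cycle_drug_cost([nivo], 23.9) > 0.0
        assert cycle_drug_cost([nivo], 24.1) == 0.0

    def test_invalid_inputs(self):
        nivo = DrugComponent("nivolumab", 1451.07, 9.0)
        with pytest.raises(ValueError):
            cycle_drug_cost([nivo], -1.0)
        with pytest.raises(ValueError):
            cycle_drug_cost([nivo], 1.0, price_multiplier=0.0)
        with pytest.raises(ValueError):
            DrugComponent("x", unit_cost=-5.0, units_per_cycle=1.0)


class TestAccrual:
    def test_all_dead_trace_leaves_only_terminal_and_ae(self, config):
        arm = config.arm_definition("sunitinib")
        tr = make_trace(p_pfs=[0.0] * 5, p_pd=[0.0] * 5)
        bd = accrue_costs(arm, tr)
        assert bd.terminal == pytest.approx(1893.0)
        assert bd.first_line == bd.subsequent == bd.supportive == 0.0
        assert bd.followup_management == 0.0
        assert bd.adverse_events == pytest.approx(0.75 * arm.ae_management_cost)

    def test_breakdown_conserves_total(self, base_result):
        for arm_res in (base_result.reference, base_result.comparator):
            bd = arm_res.breakdown
            parts = (bd.first_line + bd.subsequent + bd.supportive
                     + bd.followup_management + bd.adverse_events + bd.terminal)
            assert bd.total == pytest.approx(parts)
            assert arm_res.total_cost == pytest.approx(bd.total)

    def test_doubling_unit_costs_doubles_totals(self, config, model):
        """Currency-rescaling invariance: scaling every cost input by k
        scales each arm total and the ICER by k."""
        k = 2.0
        overrides = {p.name: k * p.base for p in config.parameter_specs()
                     if p.role == "cost"}
        res_k = model.evaluate(overrides)
        res_1 = model.base_case()
        assert res_k.reference.total_cost == pytest.approx(
            k * res_1.reference.total_cost)
        assert res_k.comparator.total_cost == pytest.approx(
            k * res_1.comparator.total_cost)
        assert res_k.icer == pytest.approx(k * res_1.icer)

    def test_multiplier_one_reproduces_base_bit_for_bit(self, model):
        a = model.base_case()
        b = model.evaluate(price_multiplier=1.0)
        assert a.reference.total_cost == b.reference.total_cost
        assert a.comparator.total_cost == b.comparator.total_cost
        assert a.icer == b.icer

    def test_total_monotone_in_horizon(self, model):
        costs = [model.evaluate(horizon_years=h).comparator.total_cost
                 for h in (5.0, 10.0, 15.0, 20.0)]
        assert np.all(np.diff(costs) > 0)


class TestICER:
    def test_rounded_table_inputs(self):
        """252,943 / 0.86 = 294,120: the published 292,945 needs unrounded
        increments."""
        ref = ArmResult("ref", 0.0, 4.41, 2.97)
        cmp_ = ArmResult("cmp", 252943.0, 5.34, 2.97 + 0.86)
        res = compute_icer(ref, cmp_)
        assert res.icer == pytest.approx(294119.77, abs=1.0)

    def test_identical_arms_flagged_equivalent(self):
        a = ArmResult("a", 100.0, 1.0, 1.0)
        b = ArmResult("b", 100.0, 1.0, 1.0)
        res = compute_icer(a, b)
        assert res.verdict == "equivalent"
        assert np.isnan(res.icer)

    def test_dominance_verdicts(self):
        ref = ArmResult("ref", 100.0, 1.0, 1.0)
        assert compute_icer(ref, ArmResult("c", 50.0, 2.0, 2.0)).verdict == \
            "dominant"
        assert compute_icer(ref, ArmResult("c", 150.0, 0.5, 0.5)).verdict == \
            "dominated"

    def test_wtp_verdict(self):
        ref = ArmResult("ref", 0.0, 0.0, 0.0)
        cheap = ArmResult("c", 30000.0, 1.0, 1.0)
        assert compute_icer(ref, cheap, wtp=38024.0).verdict == "cost_effective"
        pricey = ArmResult("p", 50000.0, 1.0, 1.0)
        assert compute_icer(ref, pricey, wtp=38024.0).verdict == \
            "not_cost_effective"


class TestNMB:
    def _result(self, dc=252943.0, de=0.86):
        ref = ArmResult("ref", 0.0, 0.0, 0.0)
        return compute_icer(ref, ArmResult("c", dc, de, de))

    def test_zero_wtp_is_negative_cost(self):
        assert net_monetary_benefit(self._result(), 0.0) == pytest.approx(
            -252943.0)

    def test_nmb_at_icer_is_zero(self):
        res = self._result()
        assert net_monetary_benefit(res, res.icer) == pytest.approx(0.0,
                                                                    abs=1e-6)

    def test_published_wtp_arithmetic(self):
        assert net_monetary_benefit(self._result(), 38024.0) == pytest.approx(
            -220242.4, abs=0.1)

    def test_negative_wtp_rejected(self):
        with pytest.raises(ValueError):
            net_monetary_benefit(self._result(), -1.0)


class TestPricingModes:
    def test_whole_unit_vs_per_mg(self, config):
        """The two pricing conventions differ exactly by the vial/tablet
        rounding factors."""
        cfg_mg = config.copy()
        cfg_mg.raw["pricing"]["mode"] = "per_mg"
        nivo_whole = config.drug_component("nivolumab")
        nivo_mg = cfg_mg.drug_component("nivolumab")
        assert nivo_whole.cycle_cost / nivo_mg.cycle_cost == pytest.approx(
            9.0 / 7.2)
        sun_whole = config.drug_component("sunitinib")
        sun_mg = cfg_mg.drug_component("sunitinib")
        assert sun_mg.cycle_cost == pytest.approx(4.0 * sun_whole.cycle_cost)
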