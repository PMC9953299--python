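"""Inverse estimators: body amounts, 24-h synthesis, demand and utilization."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

import vitd_balance as v
from vitd_balance.balance import (
    SerumPanel,
    UrineCollection,
    apply_precursor_correction,
    body_amount_from_plasma,
    demand_ratio_body,
    demand_ratio_urine,
    intermediate_buildup_check,
    synthesis_24h,
    utilization_24h,
    utilization_point,
)

conc = st.floats(0.0, 1e3)


def panel(t, **c):
    return SerumPanel(t, c)


class TestBodyAmount:
    def test_zero(self, male):
        assert body_amount_from_plasma(0.0, male) == 0.0

    def test_male_coefficient(self, male):
        # Ve·(2β+1) = 14 × 3.2 = 44.8 nmol per nmol/L
        assert body_amount_from_plasma(1.0, male) == pytest.approx(44.8)

    def test_female_coefficient(self, female):
        assert body_amount_from_plasma(1.0, female) == pytest.approx(35.2)

    def test_female_coefficient_matches_quoted_form(self, female):
        # for women Ve = 4.4·Vp exactly, so the quoted 4.4·Vp·(2β+1) agrees
        assert female.body_amount_factor == pytest.approx(4.4 * female.Vp * 3.2)

    def test_negative_rejected(self, male):
        with pytest.raises(ValueError):
            body_amount_from_plasma(-0.1, male)


class TestSynthesis24h:
    def hand_case(self, male):
        p0 = panel(0.0, m8=1.0, m9=1.0, m10=1.0)
        p1 = panel(24.0, m8=1.2, m9=1.15, m10=1.15)  # ΣΔC = 0.5 nmol/L
        urine = UrineCollection(0.0, 24.0, 2.0, {"m8": 5.0, "m9": 3.0, "m10": 2.0})
        return p0, p1, urine

    def test_hand_evaluated_example(self, male):
        # 14·3.2·0.5 + 4·(10·2) = 22.4 + 80 = 102.4 nmol
        est = synthesis_24h(*self.hand_case(male), male)
        assert est.total == pytest.approx(102.4)
        assert est.body_change_term == pytest.approx(22.4)
        assert est.excretion_term == pytest.approx(80.0)
        assert est.total == est.body_change_term + est.excretion_term
        assert not est.negative_flag
        assert est.per_24h

    def test_no_change_no_excretion_gives_zero(self, male):
        p0 = panel(0.0, m8=1.0, m9=1.0, m10=1.0)
        p1 = panel(24.0, m8=1.0, m9=1.0, m10=1.0)
        urine = UrineCollection(0.0, 24.0, 1.5, {"m8": 0.0, "m9": 0.0, "m10": 0.0})
        assert synthesis_24h(p0, p1, urine, male).total == 0.0

    def test_falling_levels_can_flag_negative(self, male):
        p0 = panel(0.0, m8=2.0, m9=2.0, m10=2.0)
        p1 = panel(24.0, m8=0.5, m9=0.5, m10=0.5)
        urine = UrineCollection(0.0, 24.0, 1.0, {"m8": 0.1, "m9": 0.1, "m10": 0.1})
        est = synthesis_24h(p0, p1, urine, male)
        assert est.total < 0 and est.negative_flag

    def test_diverted_species_uses_m6_m7(self, male):
        p0 = panel(0.0, m6=1.0, m7=1.0)
        p1 = panel(24.0, m6=1.5, m7=1.5)
        urine = UrineCollection(0.0, 24.0, 1.0, {"m6": 1.0, "m7": 1.0})
        est = synthesis_24h(p0, p1, urine, male, species="diverted_end")
        assert est.total == pytest.approx(44.8 + 8.0)

    def test_missing_metabolite_named_in_error(self, male):
        p0 = panel(0.0, m8=1.0, m9=1.0)
        p1 = panel(24.0, m8=1.0, m9=1.0, m10=1.0)
        urine = UrineCollection(0.0, 24.0, 1.0, {"m8": 0, "m9": 0, "m10": 0})
        with pytest.raises(KeyError, match="m10"):
            synthesis_24h(p0, p1, urine, male)

    def test_interval_mismatch_rejected(self, male):
        p0, p1, _ = self.hand_case(male)
        urine = UrineCollection(0.0, 23.0, 2.0, {"m8": 5.0, "m9": 3.0, "m10": 2.0})
        with pytest.raises(ValueError, match="interval"):
            synthesis_24h(p0, p1, urine, male)

    def test_non_daily_interval_not_labelled_per_24h(self, male):
        p0 = panel(0.0, m8=1.0, m9=1.0, m10=1.0)
        p1 = panel(12.0, m8=1.0, m9=1.0, m10=1.0)
        urine = UrineCollection(0.0, 12.0, 1.0, {"m8": 1.0, "m9": 1.0, "m10": 1.0})
        assert not synthesis_24h(p0, p1, urine, male).per_24h

    def test_custom_urine_fraction_changes_multiplier(self, male):
        p0, p1, urine = self.hand_case(male)
        est = synthesis_24h(p0, p1, urine, male.with_(urine_fraction=0.32))
        assert est.excretion_term == pytest.approx(20.0 / 0.32)

    @given(scale=st.floats(0.01, 100.0))
    def test_linearity_in_concentrations(self, male, scale):
        p0, p1, urine = self.hand_case(male)
        sp0 = SerumPanel(0.0, {m: c * scale for m, c in p0.concentrations.items()})
        sp1 = SerumPanel(24.0, {m: c * scale for m, c in p1.concentrations.items()})
        su = UrineCollection(0.0, 24.0, urine.volume,
                             {m: c * scale for m, c in urine.concentrations.items()})
        base = synthesis_24h(p0, p1, urine, male).total
        scaled = synthesis_24h(sp0, sp1, su, male).total
        assert scaled == pytest.approx(base * scale, rel=1e-12)


class TestDemandAndUtilization:
    def full_panel(self, c67, c810, t=0.0):
        return panel(t, m6=c67 / 2, m7=c67 / 2, m8=c810 / 3, m9=c810 / 3, m10=c810 / 3)

    def test_symmetric_pools_give_unit_ratio(self, male):
        rep = demand_ratio_body(self.full_panel(2.0, 2.0), male)
        assert rep.demand_ratio == pytest.approx(1.0)
        assert rep.utilization_percent == pytest.approx(50.0)

    def test_four_to_one_ratio_gives_80_percent(self, male):
        # M₈:₁₀ = 80 nmol, M₆:₇ = 20 nmol at the male coefficient 44.8
        rep = demand_ratio_body(self.full_panel(20 / 44.8, 80 / 44.8), male)
        assert rep.demand_ratio == pytest.approx(4.0)
        assert rep.utilization_percent == pytest.approx(80.0)
        assert rep.m1_level_estimate == pytest.approx(80.0)

    def test_zero_diverted_pool_flagged_full_utilization(self, male):
        rep = demand_ratio_body(self.full_panel(0.0, 3.0), male)
        assert rep.demand_ratio is None
        assert rep.utilization_percent == 100.0
        assert rep.reason == "diverted_pool_zero"

    def test_empty_pools_fully_undefined(self, male):
        rep = demand_ratio_body(self.full_panel(0.0, 0.0), male)
        assert rep.demand_ratio is None and rep.utilization_percent is None
        assert rep.reason == "no_end_metabolites"

    def test_urine_ratio_volume_cancels(self):
        u = UrineCollection(0.0, 24.0, 1.7,
                            {"m6": 2.0, "m7": 1.0, "m8": 6.0, "m9": 4.0, "m10": 2.0})
        rep = demand_ratio_urine(u)
        assert rep.demand_ratio == pytest.approx(4.0)
        assert rep.source == "urine_24h"

    def test_urine_all_zeros_undefined(self):
        u = UrineCollection(0.0, 24.0, 1.5, {m: 0.0 for m in v.END_METABOLITES})
        assert demand_ratio_urine(u).reason == "no_end_metabolites"

    def test_point_utilization_equals_ratio_identity(self, male):
        pan = self.full_panel(3.0, 7.0)
        ut = utilization_point(pan, male)
        dr = demand_ratio_body(pan, male).demand_ratio
        assert ut == pytest.approx(100 * dr / (1 + dr), abs=1e-9)

    def test_24h_utilization_from_estimates(self, male):
        mk = lambda total: v.SynthesisEstimate((0.0, 24.0), total, total, 0.0)
        assert utilization_24h(mk(102.4), mk(25.6)) == pytest.approx(80.0)
        assert utilization_24h(mk(5.0), mk(5.0)) == pytest.approx(50.0)
        assert utilization_24h(mk(5.0), mk(0.0)) == pytest.approx(100.0)
        assert utilization_24h(mk(0.0), mk(0.0)) is None

    def test_24h_utilization_rejects_negative_flag_and_interval_mismatch(self):
        good = v.SynthesisEstimate((0.0, 24.0), 10.0, 10.0, 0.0)
        bad = v.SynthesisEstimate((0.0, 24.0), -1.0, -1.0, 0.0)
        other = v.SynthesisEstimate((0.0, 12.0), 10.0, 10.0, 0.0)
        with pytest.raises(ValueError, match="correction"):
            utilization_24h(good, bad)
        with pytest.raises(ValueError, match="interval"):
            utilization_24h(good, other)

    @given(c67=st.floats(0.01, 100), c810=st.floats(0.01, 100), scale=st.floats(0.01, 100))
    def test_ratios_scale_invariant(self, male, c67, c810, scale):
        rep1 = demand_ratio_body(self.full_panel(c67, c810), male)
        rep2 = demand_ratio_body(self.full_panel(c67 * scale, c810 * scale), male)
        assert rep2.demand_ratio == pytest.approx(rep1.demand_ratio, rel=1e-9)
        assert rep2.utilization_percent == pytest.approx(rep1.utilization_percent, rel=1e-9)

    @given(
        c67=st.one_of(st.just(0.0), st.floats(1e-9, 100)),
        c810=st.one_of(st.just(0.0), st.floats(1e-9, 100)),
    )
    def test_utilization_identity_and_bounds(self, male, c67, c810):
        rep = demand_ratio_body(self.full_panel(c67, c810), male)
        if rep.demand_ratio is not None:
            dr = rep.demand_ratio
            assert rep.utilization_percent == pytest.approx(100 * dr / (1 + dr), abs=1e-9)
        if rep.utilization_percent is not None:
            assert 0.0 <= rep.utilization_percent <= 100.0


class TestCorrections:
    @pytest.mark.parametrize(
        "measured, serum_m0, expected, floored",
        [(50.0, 0.0, 50.0, False), (50.0, 10.0, 40.0, False), (10.0, 50.0, 0.0, True)],
    )
    def test_precursor_correction(self, measured, serum_m0, expected, floored):
        res = apply_precursor_correction(measured, serum_m0)
        assert res.value == pytest.approx(expected)
        assert res.floored is floored

    def test_precursor_correction_rejects_negative(self):
        with pytest.raises(ValueError):
            apply_precursor_correction(-1.0, 0.0)

    @pytest.mark.parametrize(
        "first, driven, discrepancy, needed",
        [(100, 100, 0.0, False), (80, 100, 0.2, True), (95, 100, 0.05, False)],
    )
    def test_buildup_check(self, first, driven, discrepancy, needed):
        rep = intermediate_buildup_check(first, driven, tolerance_fraction=0.1)
        assert rep.discrepancy_fraction == pytest.approx(discrepancy)
        assert rep.correction_needed is needed

    def test_buildup_check_inconsistent_assays(self):
        with pytest.raises(ValueError, match="inconsistent"):
            intermediate_buildup_check(10.0, 0.0)
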