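import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from vatfood.vat_scenarios import (
    SCENARIOS,
    ScenarioSpec,
    VATSchedule,
    aggregate_item_rates,
    build_scenario,
    price_change,
)


def make_schedule(md=0.08, fv=0.09, other=0.10, max_rate=0.21, country="X"):
    rates = {
        "beef": md, "lamb": md, "pork": md, "poultry": md, "milk_dairy": md,
        "fruits": fv, "vegetables": fv, "legumes": fv, "nuts": fv,
        "wheat": other,
    }
    cats = {g: "MD" for g in ("beef", "lamb", "pork", "poultry", "milk_dairy")}
    cats |= {g: "FV" for g in ("fruits", "vegetables", "legumes", "nuts")}
    cats["wheat"] = "other"
    return VATSchedule(country, rates, max_rate, cats)


class TestAggregateItemRates:
    def test_identical_rates_pass_through(self):
        out = aggregate_item_rates(
            [("lemons", 0.05, 1.0), ("limes", 0.05, 1.0)],
            {"lemons": "fruits", "limes": "fruits"},
        )
        assert out == {"fruits": 0.05}

    def test_equal_weights_give_arithmetic_mean(self):
        out = aggregate_item_rates(
            [("beef_cuts", 0.10, 1.0), ("beef_offal", 0.20, 1.0)],
            {"beef_cuts": "beef", "beef_offal": "beef"},
        )
        assert out["beef"] == pytest.approx(0.15, abs=1e-15)

    def test_weighted_mean_matches_hand_summation(self):
        items = [
            ("a", 0.05, 2.0), ("b", 0.10, 1.0), ("c", 0.21, 1.0),
            ("d", 0.00, 3.0), ("e", 0.12, 2.0), ("f", 0.27, 1.0),
        ]
        mapping = {"a": "g1", "b": "g1", "c": "g1", "d": "g2", "e": "g2", "f": "g2"}
        out = aggregate_item_rates(items, mapping)
        # independent hand summation
        g1 = (2 * 0.05 + 1 * 0.10 + 1 * 0.21) / 4.0
        g2 = (3 * 0.00 + 2 * 0.12 + 1 * 0.27) / 6.0
        assert out["g1"] == pytest.approx(g1, abs=1e-12)
        assert out["g2"] == pytest.approx(g2, abs=1e-12)

    def test_unmapped_item_and_zero_weight_group_raise(self):
        with pytest.raises(ValueError, match="no food-group mapping"):
            aggregate_item_rates([("x", 0.1, 1.0)], {})
        with pytest.raises(ValueError, match="zero"):
            aggregate_item_rates([("x", 0.1, 0.0)], {"x": "g"})


class TestBuildScenario:
    def test_zero_fv_zero_rates_the_fv_category(self):
        s = build_scenario(make_schedule(fv=0.09), ScenarioSpec("zero_fv"))
        assert all(s.group_rates[g] == 0.0 for g in s.groups_in_category("FV"))
        assert s.group_rates["wheat"] == 0.10  # untouched

    def test_country_already_at_max_is_unchanged_by_max_md(self):
        base = make_schedule(md=0.25, fv=0.25, other=0.25, max_rate=0.25)
        assert build_scenario(base, ScenarioSpec("max_md")).group_rates == base.group_rates

    def test_uk_like_md_raised_by_20pp(self):
        base = make_schedule(md=0.0, fv=0.0, other=0.0, max_rate=0.20)
        s = build_scenario(base, ScenarioSpec("max_md"))
        assert all(s.group_rates[g] == 0.20 for g in s.groups_in_category("MD"))

    @pytest.mark.parametrize("name", SCENARIOS)
    def test_idempotent(self, name):
        spec = ScenarioSpec(name)
        once = build_scenario(make_schedule(), spec)
        assert build_scenario(once, spec).group_rates == once.group_rates

    def test_combo_equals_composition_in_either_order(self):
        base = make_schedule()
        combo = build_scenario(base, ScenarioSpec("combo"))
        ab = build_scenario(
            build_scenario(base, ScenarioSpec("zero_fv")), ScenarioSpec("max_md")
        )
        ba = build_scenario(
            build_scenario(base, ScenarioSpec("max_md")), ScenarioSpec("zero_fv")
        )
        assert combo.group_rates == ab.group_rates == ba.group_rates

    def test_meat_variants_target_subsets(self):
        base = make_schedule()
        red = build_scenario(base, ScenarioSpec("max_redmeat_combo"))
        meat = build_scenario(base, ScenarioSpec("max_meat_combo"))
        assert red.group_rates["beef"] == base.max_rate
        assert red.group_rates["poultry"] == base.group_rates["poultry"]
        assert meat.group_rates["poultry"] == base.max_rate
        assert meat.group_rates["milk_dairy"] == base.group_rates["milk_dairy"]
        assert red.group_rates["fruits"] == 0.0  # combo variants zero-rate FV

    def test_rate_above_max_rejected(self):
        with pytest.raises(ValueError, match="exceeds max_rate"):
            make_schedule(md=0.30, max_rate=0.20)

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ValueError, match="unknown scenario"):
            ScenarioSpec("double_fv")


class TestPriceChange:
    def test_zero_baseline_full_passthrough_equals_rate_change(self):
        assert price_change(0.0, 0.20, 1.0) == pytest.approx(0.20, abs=1e-15)

    def test_closed_form_with_nonzero_baseline(self):
        assert price_change(0.08, 0.21, 1.0) == pytest.approx(1.21 / 1.08 - 1.0, abs=1e-15)
        assert price_change(0.08, 0.21, 1.0) == pytest.approx(0.120370370, abs=1e-9)

    @given(st.floats(0, 1), st.floats(0, 1))
    def test_no_change_identity(self, t, ptr):
        assert price_change(t, t, ptr) == 0.0

    @given(
        st.floats(0, 0.5),
        st.floats(0, 0.5),
        st.floats(0, 0.5),
        st.floats(0.01, 1),
    )
    def test_strictly_increasing_in_new_rate(self, t0, t1a, dt, ptr):
        lo = price_change(t0, t1a, ptr)
        hi = price_change(t0, t1a + dt + 1e-6, ptr)
        assert hi > lo

    def test_zero_passthrough_means_no_price_change(self):
        assert price_change(0.05, 0.25, 0.0) == 0.0
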