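"""Item screening values and the two-pass high-sensitivity selection."""

import numpy as np
import pytest

from kg7screen import item_screening_value, select_items
from kg7screen.cohort_model import Cohort
from kg7screen.item_screening import ItemScreeningValue, screen_domain

from conftest import make_record
from oracles import brute_select


def make_value(item_id, mean_se, mean_sp, domain="SGDS"):
    return ItemScreeningValue(item_id=item_id, domain=domain, per_category=(),
                              mean_se=mean_se, mean_sp=mean_sp)


class TestScreeningValue:
    def test_constructed_2x2_reproduces_shopping_metrics(self):
        """45 IADL-deficit patients of whom 41 are shopping-dependent, 29
        intact shopping-independent: SE 91.1%, SP 100%, PPV 100%, NPV 87.8%."""
        recs = []
        for i in range(41):  # deficit, shopping dependent (+ a second item)
            recs.append(make_record(f"D{i}", iadl_dependent=("shopping", "laundry")))
        for i in range(4):   # deficit without shopping dependency
            recs.append(make_record(f"E{i}", iadl_dependent=("laundry", "housekeeping")))
        for i in range(29):  # intact
            recs.append(make_record(f"N{i}"))
        v = item_screening_value(Cohort(records=recs), "iadl_shopping")
        m = v.per_category[0]
        assert round(100 * m.se, 1) == 91.1
        assert m.sp == 1.0 and m.ppv == 1.0
        assert round(100 * m.npv, 1) == 87.9  # 29/33
        assert v.balanced_accuracy == (v.mean_se + v.mean_sp) / 2

    def test_item_identical_to_case_indicator_is_perfect(self):
        recs = [make_record(f"D{i}", iadl_dependent=("shopping",)) for i in range(10)]
        recs += [make_record(f"N{i}") for i in range(10)]
        v = item_screening_value(Cohort(records=recs), "iadl_shopping")
        assert v.mean_se == 1.0 and v.mean_sp == 1.0

    def test_two_category_domain_uses_category_vs_rest(self):
        """Mild and severe analyses share the item but not the non-case
        group, so their specificities can differ."""
        recs = [make_record(f"M{i}", mmse_total=20) for i in range(10)]
        recs += [make_record(f"S{i}", mmse_total=10) for i in range(10)]
        recs += [make_record(f"I{i}") for i in range(10)]
        v = item_screening_value(Cohort(records=recs), "mmse_attention_calculation")
        mild, severe = v.per_category
        assert mild.category == "mild" and severe.category == "severe"
        assert mild.n_noncases == 20 and severe.n_noncases == 20
        assert v.mean_se == (mild.se + severe.se) / 2

    def test_zero_case_category_flagged_not_fatal(self):
        recs = [make_record(f"I{i}") for i in range(5)]
        recs += [make_record("M1", mmse_total=20)]
        v = item_screening_value(Cohort(records=recs), "mmse_recall")
        mild, severe = v.per_category
        assert severe.se is None and not severe.defined
        assert mild.defined  # the mean runs over the defined category only
        assert v.mean_se == mild.se

    def test_shopping_sensitivity_on_calibrated_cohort(self, screening_cohort):
        """On cohorts calibrated to the development registry's operating
        characteristics the shopping item carries ~91% sensitivity."""
        cohort, _ = screening_cohort
        v = item_screening_value(cohort, "iadl_shopping")
        assert v.mean_se == pytest.approx(0.911, abs=0.04)
        assert v.mean_sp == 1.0  # intact patients are shopping-independent


class TestSelectItems:
    def test_top2_balanced_accuracy_among_high_se(self):
        vals = [make_value("sgds_dropped_activities", 0.93, 2 * 0.752 - 0.93),
                make_value("sgds_full_of_energy", 0.92, 2 * 0.770 - 0.92),
                make_value("sgds_good_spirits", 0.95, 2 * 0.552 - 0.95)]
        res = select_items(vals)
        assert res.selected == ("sgds_full_of_energy", "sgds_dropped_activities")
        assert res.threshold_used == 0.90 and not res.shortfall

    def test_widening_to_80_when_only_one_passes_90(self):
        vals = [make_value("adl_bathing", 0.942, 0.80, domain="ADL"),
                make_value("adl_stairs", 0.852, 0.85, domain="ADL"),
                make_value("adl_feeding", 0.50, 0.90, domain="ADL")]
        res = select_items(vals)
        assert res.threshold_used == 0.80
        assert set(res.selected) == {"adl_bathing", "adl_stairs"}

    def test_feasibility_exclusions_force_widening(self):
        vals = [make_value("mmse_attention_calculation", 0.981, 0.511, domain="MMSE"),
                make_value("mmse_recall", 0.949, 0.281, domain="MMSE"),
                make_value("mmse_complex_commands", 0.88, 0.40, domain="MMSE"),
                make_value("mmse_orientation_time", 0.85, 0.55, domain="MMSE"),
                make_value("mmse_orientation_place", 0.83, 0.50, domain="MMSE")]
        excl = {"mmse_attention_calculation": "not feasible",
                "mmse_recall": "not feasible",
                "mmse_complex_commands": "low feasibility"}
        res = select_items(vals, feasibility_exclusions=excl)
        assert set(res.selected) == {"mmse_orientation_time", "mmse_orientation_place"}
        assert res.threshold_used == 0.80
        assert set(res.excluded_by_feasibility) == set(excl)

    def test_all_below_80_yields_shortfall(self):
        vals = [make_value("a", 0.7, 0.9), make_value("b", 0.6, 0.9)]
        res = select_items(vals)
        assert res.selected == () and res.shortfall

    def test_empty_input_is_usage_error(self):
        with pytest.raises(ValueError):
            select_items([])

    def test_mixed_domains_rejected(self):
        with pytest.raises(ValueError, match="domains"):
            select_items([make_value("a", 0.95, 0.5, domain="ADL"),
                          make_value("b", 0.95, 0.5, domain="MNA")])

    def test_order_invariance_and_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            n = int(rng.integers(1, 9))
            vals = [make_value(f"item{j}", float(rng.integers(50, 101)) / 100,
                               float(rng.integers(0, 101)) / 100) for j in range(n)]
            excl = {v.item_id: "x" for v in vals if rng.random() < 0.2}
            res = select_items(vals, feasibility_exclusions=excl)
            assert res.selected == brute_select(vals, excl)
            shuffled = list(vals)
            rng.shuffle(shuffled)
            assert select_items(shuffled, feasibility_exclusions=excl).selected == res.selected


def test_screen_domain_covers_registered_items():
    recs = [make_record(f"P{i}", mmse_total=20 if i % 2 else 30) for i in range(6)]
    vals = screen_domain(Cohort(records=recs), "MMSE")
    ids = {v.item_id for v in vals}
    assert "mmse_orientation_time" in ids and "mmse_attention_calculation" in ids
    assert all(v.domain == "MMSE" for v in vals)
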