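"""Cross-tables, accuracy metrics, Mann-Whitney AUC, cut-off selection."""

from fractions import Fraction

import numpy as np
import pytest

from kg7screen.diagnostics import (
    ConfusionTable,
    ScoreCrossTable,
    confusion_at_cutoff,
    cross_table,
    diagnostic_metrics,
    empirical_auc,
    roc_points,
    select_cutoff,
)
from kg7screen.synthetic_cohort import generate_crosstable_cohort

from oracles import brute_auc, brute_best_cutoff, brute_confusion, expand_table


def random_table(rng):
    k = int(rng.integers(2, 7))
    levels = tuple(range(k))
    cases = tuple(int(x) for x in rng.integers(0, 12, size=k))
    controls = tuple(int(x) for x in rng.integers(0, 12, size=k))
    if sum(cases) == 0:
        cases = cases[:-1] + (1,)
    if sum(controls) == 0:
        controls = (1,) + controls[1:]
    return ScoreCrossTable(levels, cases, controls)


class TestCrossTable:
    def test_expand_then_tabulate_is_identity(self, table3):
        df = generate_crosstable_cohort(table3, seed=9)
        scores = dict(zip(df.patient_id, df.score))
        ref = dict(zip(df.patient_id, df.reference))
        out = cross_table(scores, ref)
        assert out.levels == table3.levels
        assert out.cases == table3.cases and out.controls == table3.controls
        assert out.n_total == sum(table3.cases) + sum(table3.controls)

    def test_indeterminate_and_missing_dropped_with_count(self):
        scores = {"a": 3, "b": None, "c": 7, "d": 2}
        ref = {"a": True, "b": True, "c": False, "d": None, "e": True}
        out = cross_table(scores, ref)
        assert out.n_total == 2 and out.n_dropped == 3

    def test_single_level_table(self):
        out = cross_table({"a": 4, "b": 4}, {"a": True, "b": False})
        assert out.levels == (4,) and out.cases == (1,) and out.controls == (1,)

    def test_disjoint_patients_is_usage_error(self):
        with pytest.raises(ValueError):
            cross_table({"a": 1}, {"b": True})


class TestConfusion:
    def test_development_fixture_at_cutoff_5(self, table3):
        ct = confusion_at_cutoff(table3, 5)
        assert (ct.tp, ct.fp, ct.fn, ct.tn) == (725, 125, 38, 181)

    def test_max_cutoff_leaves_no_negatives(self, table3):
        ct = confusion_at_cutoff(table3, 7)
        assert ct.fn == 0 and ct.tn == 0

    def test_perfectly_separated_table(self):
        t = ScoreCrossTable((0, 7), (10, 0), (0, 5))
        ct = confusion_at_cutoff(t, 0)
        assert ct.tp == 10 and ct.tn == 5 and ct.fp == 0 and ct.fn == 0


class TestMetrics:
    def test_development_fixture_reproduces_printed_values(self, table3):
        m = diagnostic_metrics(confusion_at_cutoff(table3, 5))
        assert round(100 * m.sensitivity.value, 1) == 95.0
        assert round(100 * m.specificity.value, 1) == 59.2
        assert round(100 * m.ppv.value, 1) == 85.3
        assert round(100 * m.npv.value, 1) == 82.6
        assert round(100 * m.sensitivity.lower, 1) == 93.5
        assert round(100 * m.screen_normal_fraction, 1) == 20.5

    def test_perfect_classifier_truncates_ci(self):
        m = diagnostic_metrics(ConfusionTable(tp=10, fp=0, fn=0, tn=10))
        for metric in (m.sensitivity, m.specificity, m.ppv, m.npv):
            assert metric.value == 1.0 and metric.upper == 1.0
        assert m.balanced_accuracy == 1.0

    def test_zero_denominator_is_undefined_not_fatal(self):
        m = diagnostic_metrics(ConfusionTable(tp=0, fp=0, fn=0, tn=10))
        assert m.sensitivity.value is None and m.ppv.value is None
        assert m.specificity.value == 1.0


class TestAUC:
    def test_development_fixture_exact_rational(self, table3):
        res = empirical_auc(table3)
        assert res.auc == pytest.approx(float(Fraction(434463, 466956)), abs=1e-12)
        assert round(res.auc, 2) == 0.93

    def test_identical_distributions_give_half(self):
        t = ScoreCrossTable((0, 1, 2), (5, 10, 5), (10, 20, 10))
        assert empirical_auc(t).auc == 0.5

    def test_perfect_separation_gives_one(self):
        t = ScoreCrossTable((0, 7), (10, 0), (0, 10))
        assert empirical_auc(t).auc == 1.0

    def test_degenerate_table_raises(self):
        with pytest.raises(ValueError):
            empirical_auc(ScoreCrossTable((0,), (5,), (0,)))

    def test_matches_trapezoid_under_roc(self, table3):
        pts = roc_points(table3)
        x = [p[0] for p in pts]
        y = [p[1] for p in pts]
        assert empirical_auc(table3).auc == pytest.approx(np.trapezoid(y, x), abs=1e-12)


class TestSelectCutoff:
    def test_development_fixture_selects_5_under_se_constraint(self, table3):
        res = select_cutoff(table3, min_sensitivity=0.90)
        assert res.cutoff == 5 and res.constraint_met

    def test_unconstrained_is_plain_youden(self, table3):
        res = select_cutoff(table3, min_sensitivity=0.0)
        rows = expand_table(table3.levels, table3.cases, table3.controls)
        assert res.cutoff == brute_best_cutoff(rows, table3.levels, 0.0)

    def test_perfectly_separated_table_finds_separator(self):
        t = ScoreCrossTable((0, 3, 7), (8, 2, 0), (0, 0, 5))
        assert select_cutoff(t, min_sensitivity=0.99).cutoff == 3

    def test_constraint_always_reachable_at_top_cutoff(self):
        # at the highest score level every case screens positive (SE = 1),
        # so a floor <= 1 can always be met
        t = ScoreCrossTable((0, 1), (5, 5), (0, 10))
        res = select_cutoff(t, min_sensitivity=1.0)
        assert res.constraint_met and res.cutoff == 1
        with pytest.raises(ValueError):
            select_cutoff(t, min_sensitivity=1.5)

    def test_sensitivity_monotone_specificity_antitone(self, table3):
        prev_se, prev_sp = -1.0, 2.0
        for lv in table3.levels:
            ct = confusion_at_cutoff(table3, lv)
            se = ct.tp / (ct.tp + ct.fn)
            sp = ct.tn / (ct.fp + ct.tn)
            assert se >= prev_se and sp <= prev_sp
            prev_se, prev_sp = se, sp


def test_oracle_equivalence_on_random_tables():
    """All diagnostics agree with brute-force pairwise computation."""
    rng = np.random.default_rng(20150924)
    for _ in range(100):
        t = random_table(rng)
        rows = expand_table(t.levels, t.cases, t.controls)
        cut = int(t.levels[int(rng.integers(0, len(t.levels)))])
        ct = confusion_at_cutoff(t, cut)
        assert (ct.tp, ct.fp, ct.fn, ct.tn) == brute_confusion(rows, cut)
        assert empirical_auc(t).auc == pytest.approx(brute_auc(rows), abs=1e-12)
        assert select_cutoff(t, 0.8).cutoff == brute_best_cutoff(rows, t.levels, 0.8) \
            or not select_cutoff(t, 0.8).constraint_met
        pts = roc_points(t)
        assert empirical_auc(t).auc == pytest.approx(
            np.trapezoid([p[1] for p in pts], [p[0] for p in pts]), abs=1e-12)
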