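"""Domain categorization thresholds and the tri-state reference labels."""

import itertools

import pytest

from kg7screen.ga_domains import REFERENCE_DOMAINS, categorize_domain, classify_ga

from conftest import make_record
from oracles import brute_ga_flags


@pytest.mark.parametrize("kwargs,domain,expected", [
    # MMSE bands: <=16 severe, 17-24 mild, >=25 intact
    (dict(mmse_total=16), "MMSE", "severe"),
    (dict(mmse_total=17), "MMSE", "mild"),
    (dict(mmse_total=24), "MMSE", "mild"),
    (dict(mmse_total=25), "MMSE", "intact"),
    # SGDS: >=10 severe, 5-9 mild
    (dict(sgds_total=10), "SGDS", "severe"),
    (dict(sgds_total=9), "SGDS", "mild"),
    (dict(sgds_total=5), "SGDS", "mild"),
    (dict(sgds_total=4), "SGDS", "intact"),
    # MNA: <17 malnutrition, 17-23.5 at risk, >=24 normal
    (dict(mna_total=16.5), "MNA", "severe"),
    (dict(mna_total=17.0), "MNA", "mild"),
    (dict(mna_total=23.5), "MNA", "mild"),
    (dict(mna_total=24.0), "MNA", "intact"),
    # TGUG: impairment strictly above 20 s; severe from 25 s
    (dict(tgug=20.0), "TGUG", "intact"),
    (dict(tgug=20.1), "TGUG", "mild"),
    (dict(tgug=24.9), "TGUG", "mild"),
    (dict(tgug=25.0), "TGUG", "severe"),
    # ADL: any dependency is a deficit; total <=75 severe
    (dict(adl_total=100), "ADL", "intact"),
    (dict(adl_total=95, adl_dependent_items=("bathing",)), "ADL", "mild"),
    (dict(adl_total=80), "ADL", "mild"),
    (dict(adl_total=75), "ADL", "severe"),
])
def test_category_thresholds(kwargs, domain, expected):
    rec = make_record("P", **kwargs)
    assert categorize_domain(rec, domain).category == expected


@pytest.mark.parametrize("sex,n_dep,expected", [
    ("male", 0, "intact"),
    ("male", 1, "mild"),     # 4 of 5 independent
    ("male", 2, "severe"),   # <=3 independent
    ("female", 1, "mild"),   # 7 of 8 independent
    ("female", 2, "severe"),  # <=6 independent
    ("female", 8, "severe"),
])
def test_iadl_thresholds_by_sex(sex, n_dep, expected):
    from kg7screen.cohort_model import IADL_ITEMS_FEMALE, IADL_ITEMS_MALE
    items = IADL_ITEMS_MALE if sex == "male" else IADL_ITEMS_FEMALE
    rec = make_record("P", sex=sex, iadl_dependent=items[:n_dep])
    assert categorize_domain(rec, "IADL").category == expected


@pytest.mark.parametrize("points,band", [
    (0, "low"), (1, "medium"), (2, "medium"), (3, "high"), (4, "high"),
    (5, "very_high"), (11, "very_high"),
])
def test_charlson_bands_descriptive(points, band):
    rec = make_record("P", charlson=points)
    status = categorize_domain(rec, "CHARLSON")
    assert status.band == band
    assert "CHARLSON" not in REFERENCE_DOMAINS


@pytest.mark.parametrize("field,nc_flag", [
    ("mmse", "mmse_not_capable"),
    ("sgds", "sgds_not_capable"),
    ("mna", "mna_not_capable"),
    ("tgug", "tgug_not_capable"),
])
def test_not_capable_is_severe_not_missing(field, nc_flag):
    rec = make_record("P")
    setattr(rec, nc_flag, True)
    if field != "tgug":
        setattr(rec, f"{field}_items", None)
    else:
        rec.tgug_seconds = None
    assert categorize_domain(rec, field.upper()).category == "severe"


class TestClassifyGA:
    def test_two_mild_deficits_is_abnormal(self):
        rec = make_record("P", mmse_total=20, sgds_total=6)
        cls = classify_ga(rec)
        assert cls.n_deficits == 2 and cls.abnormal_ga is True
        assert cls.severe_any is False

    def test_single_deficit_is_normal(self):
        rec = make_record("P", mmse_total=20)
        assert classify_ga(rec).abnormal_ga is False

    def test_one_deficit_one_missing_is_indeterminate(self):
        rec = make_record("P", mmse_total=20)
        rec.tgug_seconds = None
        cls = classify_ga(rec)
        assert cls.abnormal_ga is None and cls.n_missing == 1

    def test_five_intact_one_missing_is_decidably_normal(self):
        rec = make_record("P")
        rec.mna_items = None
        cls = classify_ga(rec)
        assert cls.abnormal_ga is False  # at most 1 deficit is reachable
        assert cls.severe_any is None    # the missing domain could be severe

    def test_severe_any_implies_a_deficit(self, small_cohort):
        cohort, _ = small_cohort
        for rec in cohort:
            cls = classify_ga(rec)
            if cls.severe_any is True:
                assert cls.n_deficits >= 1


def _record_with_pattern(pattern):
    """Realize a (category per domain) pattern on a concrete record."""
    by_dom = dict(zip(REFERENCE_DOMAINS, pattern))
    kwargs = {}
    val = {
        "ADL": {"intact": dict(), "mild": dict(adl_total=90, adl_dependent_items=("bathing",)),
                "severe": dict(adl_total=50)},
        "MMSE": {"intact": dict(), "mild": dict(mmse_total=20), "severe": dict(mmse_total=10)},
        "SGDS": {"intact": dict(), "mild": dict(sgds_total=6), "severe": dict(sgds_total=12)},
        "MNA": {"intact": dict(), "mild": dict(mna_total=20.0), "severe": dict(mna_total=10.0)},
        "TGUG": {"intact": dict(), "mild": dict(tgug=22.0), "severe": dict(tgug=30.0)},
    }
    for dom in ("ADL", "MMSE", "SGDS", "MNA", "TGUG"):
        if by_dom[dom] != "missing":
            kwargs.update(val[dom][by_dom[dom]])
    iadl_dep = {"intact": (), "mild": ("shopping",),
                "severe": ("shopping", "laundry"), "missing": ()}[by_dom["IADL"]]
    rec = make_record("P", sex="female", iadl_dependent=iadl_dep, **kwargs)
    if by_dom["ADL"] == "missing":
        rec.adl_items = None
    if by_dom["IADL"] == "missing":
        rec.iadl_items = None
    if by_dom["MMSE"] == "missing":
        rec.mmse_items = None
    if by_dom["SGDS"] == "missing":
        rec.sgds_items = None
    if by_dom["MNA"] == "missing":
        rec.mna_items = None
    if by_dom["TGUG"] == "missing":
        rec.tgug_seconds = None
    return rec


def test_determinacy_equals_exhaustive_enumeration():
    """Tri-state flags agree with brute-force enumeration over every
    completion of the missing domains, for all 4^6 status patterns."""
    cats = ("intact", "mild", "severe", "missing")
    for pattern in itertools.product(cats, repeat=6):
        rec = _record_with_pattern(pattern)
        cls = classify_ga(rec)
        got_pattern = tuple(cls.statuses[d].category for d in REFERENCE_DOMAINS)
        assert got_pattern == pattern  # the record realizes the pattern
        exp_abn, exp_sev = brute_ga_flags(pattern)
        assert cls.abnormal_ga == exp_abn, pattern
        assert cls.severe_any == exp_sev, pattern


@pytest.mark.parametrize("domain,worse,better", [
    ("MMSE", dict(mmse_total=15), dict(mmse_total=28)),
    ("SGDS", dict(sgds_total=12), dict(sgds_total=2)),
    ("MNA", dict(mna_total=10.0), dict(mna_total=28.0)),
    ("TGUG", dict(tgug=40.0), dict(tgug=12.0)),
    ("ADL", dict(adl_total=40), dict(adl_total=100)),
])
def test_monotone_in_raw_total(domain, worse, better):
    order = {"intact": 0, "mild": 1, "severe": 2}
    cw = categorize_domain(make_record("P", **worse), domain).category
    cb = categorize_domain(make_record("P", **better), domain).category
    assert order[cw] >= order[cb]
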