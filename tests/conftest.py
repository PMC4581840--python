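"""Shared fixtures: the packaged development cross-table and seeded
synthetic cohorts (session-scoped; generation is the expensive part)."""

from __future__ import annotations

import pytest

from kg7screen import SyntheticConfig, generate_cohort
from kg7screen.cohort_model import (
    ADL_ITEM_MAX,
    GARecord,
    IADL_ITEMS_FEMALE,
    IADL_ITEMS_MALE,
    MMSE_COMPONENT_MAX,
    MNA_ITEM_MAX,
    SGDS_ITEMS,
)
from kg7screen.diagnostics import development_crosstable


@pytest.fixture(scope="session")
def table3():
    return development_crosstable()


@pytest.fixture(scope="session")
def small_cohort():
    """1000-patient default-condition cohort, fixed seed."""
    cohort, truth = generate_cohort(SyntheticConfig(n_patients=1000, seed=20150924))
    return cohort, truth


@pytest.fixture(scope="session")
def screening_cohort():
    """Larger cohort for item-screening rate checks, fixed seed."""
    cohort, truth = generate_cohort(SyntheticConfig(n_patients=8000, seed=7))
    return cohort, truth


def make_record(pid="P1", sex="female", *, adl_total=100, adl_dependent_items=(),
                iadl_dependent=(), mmse_total=30, sgds_total=0, mna_total=30.0,
                tgug=10.0, charlson=0, n_drugs=2, **overrides) -> GARecord:
    """Hand-build a record whose domain totals land where the test needs.

    Totals are realized on concrete items: ADL deducts from the listed
    dependent items (topping up from the rest), MMSE/SGDS/MNA deduct in a
    fixed item order.  Explicit field overrides win.
    """
    adl = {k: float(v) for k, v in ADL_ITEM_MAX.items()}
    loss = 100 - adl_total
    order = list(adl_dependent_items) + [k for k in ADL_ITEM_MAX
                                         if k not in adl_dependent_items]
    for k in adl_dependent_items:
        if loss >= 5:
            adl[k] -= 5
            loss -= 5
    for k in order:
        while loss >= 5 and adl[k] >= 5:
            adl[k] -= 5
            loss -= 5

    names = IADL_ITEMS_MALE if sex == "male" else IADL_ITEMS_FEMALE
    iadl = {k: ("dependent" if k in iadl_dependent else "independent") for k in names}

    mmse = {k: float(v) for k, v in MMSE_COMPONENT_MAX.items()}
    loss = 30 - mmse_total
    for k in ("attention_calculation", "recall", "language", "complex_commands",
              "orientation_place", "orientation_time_date", "orientation_time_other",
              "registration"):
        take = min(loss, mmse[k])
        mmse[k] -= take
        loss -= take

    sgds = {k: 0 for k in SGDS_ITEMS}
    for k in list(SGDS_ITEMS)[:sgds_total]:
        sgds[k] = 1

    mna = {k: float(v[0]) for k, v in MNA_ITEM_MAX.items()}
    loss = 30.0 - mna_total
    for k in mna:
        take = min(loss, mna[k])
        mna[k] -= take
        loss -= take

    rec = GARecord(
        patient_id=pid, age=77, sex=sex,
        adl_items=adl, iadl_items=iadl, mmse_items=mmse,
        sgds_items=sgds, mna_items=mna,
        tgug_seconds=tgug, charlson_points=charlson, n_drugs=n_drugs,
    )
    for k, v in overrides.items():
        setattr(rec, k, v)
    rec.validate()
    return rec
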