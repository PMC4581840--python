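"""Patient-level geriatric-assessment (GA) records and cohort I/O.

A :class:`GARecord` carries the raw item-level responses of the six GA
instruments used as the reference standard (Barthel ADL, Lawton-Brody IADL,
MMSE-KC, SGDS, MNA, TGUG) plus comorbidity, polypharmacy, demographics and
overall-survival follow-up.  Cohorts round-trip through a flat CSV table
whose column dictionary ships with the package
(``kg7screen/data/cohort_schema.json``).

Missing and "not capable" are distinct states throughout: a missing field
means the instrument was not administered and propagates to a missing
domain category; "NC" is an observed response (the patient could not
perform the task) and is treated as severe impairment downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterator, Mapping

import pandas as pd

__all__ = [
    "ADL_ITEM_MAX",
    "IADL_ITEMS_MALE",
    "IADL_ITEMS_FEMALE",
    "MMSE_COMPONENT_MAX",
    "SGDS_ITEMS",
    "MNA_ITEM_MAX",
    "GARecord",
    "Cohort",
    "CohortValidationError",
    "read_cohort",
    "write_cohort",
    "load_schema",
]

#: Barthel ADL items with their maximum (fully independent) weights; total 0-100.
ADL_ITEM_MAX: dict[str, int] = {
    "feeding": 10,
    "bathing": 5,
    "grooming": 5,
    "dressing": 10,
    "bowels": 10,
    "bladder": 10,
    "toilet_use": 10,
    "transfers": 15,
    "walking": 15,
    "stairs": 10,
}

#: Lawton-Brody IADL items; the first five apply to everyone, women are
#: additionally assessed on food preparation, laundry and housekeeping.
IADL_ITEMS_MALE: tuple[str, ...] = (
    "telephone",
    "shopping",
    "transportation",
    "medication",
    "finances",
)
IADL_ITEMS_FEMALE: tuple[str, ...] = IADL_ITEMS_MALE + (
    "food_preparation",
    "laundry",
    "housekeeping",
)
IADL_RESPONSES = ("independent", "dependent", "not_capable")

#: MMSE-KC component sub-scores (this package's component map; totals 0-30).
#: Orientation-to-time is split so that the date part (year/month/day) is
#: addressable: it is the source of KG-7 question 6.
MMSE_COMPONENT_MAX: dict[str, int] = {
    "orientation_time_date": 3,   # year, month, day
    "orientation_time_other": 2,  # weekday, season
    "orientation_place": 5,
    "registration": 3,
    "attention_calculation": 5,
    "recall": 3,
    "language": 6,
    "complex_commands": 3,
}

#: Short-form Geriatric Depression Scale: 15 binary items, 1 = depressive
#: response (total 0-15, higher = more depressive).
SGDS_ITEMS: tuple[str, ...] = (
    "satisfied_with_life",
    "dropped_activities",
    "life_empty",
    "often_bored",
    "good_spirits",
    "afraid_bad_things",
    "happy_most_time",
    "feel_helpless",
    "prefer_stay_home",
    "memory_problems",
    "wonderful_to_be_alive",
    "feel_worthless",
    "full_of_energy",
    "situation_hopeless",
    "others_better_off",
)

#: Mini Nutritional Assessment items mapped to (max points, step).
#: Higher = better nourished; full-scale total 0-30 in 0.5 steps.
MNA_ITEM_MAX: dict[str, tuple[float, float]] = {
    "food_intake_decline": (2, 1),
    "weight_loss": (3, 1),
    "mobility": (2, 1),
    "psych_stress": (2, 2),
    "neuropsych_problems": (2, 1),
    "bmi": (3, 1),
    "lives_independently": (1, 1),
    "more_than_3_drugs": (1, 1),   # 1 = does NOT take >3 prescription drugs/day
    "pressure_sores": (1, 1),
    "full_meals": (2, 1),
    "protein_intake": (1, 0.5),
    "fruits_vegetables": (1, 1),
    "fluid_intake": (1, 0.5),
    "feeding_mode": (2, 1),
    "self_view_nutrition": (2, 1),  # 2 = views own nutritional status as good
    "health_comparison": (2, 0.5),
    "mid_arm_circumference": (1, 0.5),
    "calf_circumference": (1, 1),
}


class CohortValidationError(ValueError):
    """Raised when a cohort table violates the record invariants."""


def _iadl_items_for(sex: str | None) -> tuple[str, ...]:
    if sex == "male":
        return IADL_ITEMS_MALE
    if sex == "female":
        return IADL_ITEMS_FEMALE
    return IADL_ITEMS_FEMALE  # unknown sex: accept the widest item set


@dataclass
class GARecord:
    """One patient's raw GA responses, demographics and follow-up.

    Any field may be ``None`` (unassessed).  ``*_not_capable`` flags record
    that the patient could not complete the whole instrument; in that case
    the corresponding item dict is ``None`` as well.
    """

    patient_id: str
    age: int | None = None
    sex: str | None = None  # "male" | "female"
    adl_items: dict[str, float] | None = None
    iadl_items: dict[str, str] | None = None
    mmse_items: dict[str, float] | None = None
    mmse_not_capable: bool = False
    sgds_items: dict[str, int] | None = None
    sgds_not_capable: bool = False
    mna_items: dict[str, float] | None = None
    mna_not_capable: bool = False
    tgug_seconds: float | None = None
    tgug_not_capable: bool = False
    charlson_points: int | None = None
    n_drugs: int | None = None
    os_time: float | None = None
    os_event: bool | None = None  # True = death observed

    # -- derived totals ----------------------------------------------------
    @property
    def adl_total(self) -> float | None:
        if self.adl_items is None:
            return None
        return sum(self.adl_items.values())

    @property
    def iadl_independent_count(self) -> int | None:
        if self.iadl_items is None:
            return None
        return sum(1 for v in self.iadl_items.values() if v == "independent")

    @property
    def mmse_total(self) -> float | None:
        if self.mmse_items is None:
            return None
        return sum(self.mmse_items.values())

    @property
    def sgds_total(self) -> int | None:
        if self.sgds_items is None:
            return None
        return int(sum(self.sgds_items.values()))

    @property
    def mna_total(self) -> float | None:
        if self.mna_items is None:
            return None
        return sum(self.mna_items.values())

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        """Check all record invariants; raise :class:`CohortValidationError`."""
        pid = self.patient_id
        if self.sex not in (None, "male", "female"):
            raise CohortValidationError(f"{pid}: sex must be male/female, got {self.sex!r}")
        if self.age is not None and not 0 <= self.age <= 130:
            raise CohortValidationError(f"{pid}: implausible age {self.age}")
        if self.adl_items is not None:
            for k, v in self.adl_items.items():
                if k not in ADL_ITEM_MAX:
                    raise CohortValidationError(f"{pid}: unknown ADL item {k!r}")
                if not 0 <= v <= ADL_ITEM_MAX[k]:
                    raise CohortValidationError(
                        f"{pid}: ADL item {k}={v} outside [0, {ADL_ITEM_MAX[k]}]"
                    )
            if not 0 <= self.adl_total <= 100:
                raise CohortValidationError(f"{pid}: ADL total {self.adl_total} outside [0,100]")
        if self.iadl_items is not None:
            expected = _iadl_items_for(self.sex)
            if self.sex in ("male", "female") and set(self.iadl_items) != set(expected):
                raise CohortValidationError(
                    f"{pid}: IADL items must be exactly {sorted(expected)} for sex={self.sex}"
                )
            for k, v in self.iadl_items.items():
                if v not in IADL_RESPONSES:
                    raise CohortValidationError(f"{pid}: IADL item {k}={v!r} invalid")
        if self.mmse_items is not None:
            for k, v in self.mmse_items.items():
                if k not in MMSE_COMPONENT_MAX:
                    raise CohortValidationError(f"{pid}: unknown MMSE component {k!r}")
                if not 0 <= v <= MMSE_COMPONENT_MAX[k]:
                    raise CohortValidationError(f"{pid}: MMSE component {k}={v} out of range")
            if not 0 <= self.mmse_total <= 30:
                raise CohortValidationError(f"{pid}: MMSE total {self.mmse_total} outside [0,30]")
        if self.sgds_items is not None:
            for k, v in self.sgds_items.items():
                if k not in SGDS_ITEMS:
                    raise CohortValidationError(f"{pid}: unknown SGDS item {k!r}")
                if v not in (0, 1):
                    raise CohortValidationError(f"{pid}: SGDS item {k}={v} not binary")
            if not 0 <= self.sgds_total <= 15:
                raise CohortValidationError(f"{pid}: SGDS total outside [0,15]")
        if self.mna_items is not None:
            for k, v in self.mna_items.items():
                if k not in MNA_ITEM_MAX:
                    raise CohortValidationError(f"{pid}: unknown MNA item {k!r}")
                if not 0 <= v <= MNA_ITEM_MAX[k][0]:
                    raise CohortValidationError(f"{pid}: MNA item {k}={v} out of range")
            if not 0 <= self.mna_total <= 30:
                raise CohortValidationError(f"{pid}: MNA total {self.mna_total} outside [0,30]")
        if self.tgug_seconds is not None and self.tgug_seconds < 0:
            raise CohortValidationError(f"{pid}: negative TGUG time")
        if self.charlson_points is not None and self.charlson_points < 0:
            raise CohortValidationError(f"{pid}: negative Charlson points")
        if self.n_drugs is not None and self.n_drugs < 0:
            raise CohortValidationError(f"{pid}: negative drug count")
        if self.os_time is not None and self.os_time < 0:
            raise CohortValidationError(f"{pid}: negative survival time")


@dataclass
class Cohort:
    """An ordered collection of :class:`GARecord` with unique patient ids."""

    records: list[GARecord] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [r.patient_id for r in self.records]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise CohortValidationError(f"duplicate patient_id(s): {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[GARecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> GARecord:
        return self.records[i]


# ---------------------------------------------------------------------------
# CSV serialization
# ---------------------------------------------------------------------------

_NC = "NC"


def load_schema() -> dict:
    """Return the packaged cohort column dictionary."""
    with resources.files("kg7screen.data").joinpath("cohort_schema.json").open() as fh:
        return json.load(fh)


def _columns() -> list[str]:
    cols = ["patient_id", "age", "sex"]
    cols += [f"adl_{k}" for k in ADL_ITEM_MAX]
    cols += [f"iadl_{k}" for k in IADL_ITEMS_FEMALE]
    cols += [f"mmse_{k}" for k in MMSE_COMPONENT_MAX] + ["mmse_nc"]
    cols += [f"sgds_{k}" for k in SGDS_ITEMS] + ["sgds_nc"]
    cols += [f"mna_{k}" for k in MNA_ITEM_MAX] + ["mna_nc"]
    cols += ["tgug_seconds", "charlson_points", "n_drugs", "os_time", "os_event"]
    return cols


def _fmt(v: float | int | None) -> str:
    if v is None:
        return ""
    if isinstance(v, float) and v == int(v):
        return str(int(v))
    return str(v)


def _record_to_row(r: GARecord) -> dict[str, str]:
    row = {c: "" for c in _columns()}
    row["patient_id"] = r.patient_id
    row["age"] = _fmt(r.age)
    row["sex"] = r.sex or ""
    if r.adl_items is not None:
        for k, v in r.adl_items.items():
            row[f"adl_{k}"] = _fmt(v)
    if r.iadl_items is not None:
        for k, v in r.iadl_items.items():
            row[f"iadl_{k}"] = _NC if v == "not_capable" else v
    if r.mmse_not_capable:
        row["mmse_nc"] = _NC
    elif r.mmse_items is not None:
        for k, v in r.mmse_items.items():
            row[f"mmse_{k}"] = _fmt(v)
    if r.sgds_not_capable:
        row["sgds_nc"] = _NC
    elif r.sgds_items is not None:
        for k, v in r.sgds_items.items():
            row[f"sgds_{k}"] = _fmt(v)
    if r.mna_not_capable:
        row["mna_nc"] = _NC
    elif r.mna_items is not None:
        for k, v in r.mna_items.items():
            row[f"mna_{k}"] = _fmt(v)
    if r.tgug_not_capable:
        row["tgug_seconds"] = _NC
    else:
        row["tgug_seconds"] = _fmt(r.tgug_seconds)
    row["charlson_points"] = _fmt(r.charlson_points)
    row["n_drugs"] = _fmt(r.n_drugs)
    row["os_time"] = _fmt(r.os_time)
    if r.os_event is not None:
        row["os_event"] = "death" if r.os_event else "censored"
    return row


def _parse_num(cell: str, *, field_name: str, rownum: int, integer: bool = False):
    if cell in ("", "NA"):
        return None
    try:
        val = float(cell)
    except ValueError as exc:
        raise CohortValidationError(
            f"row {rownum}: field {field_name!r}: cannot parse {cell!r}"
        ) from exc
    if integer:
        if val != int(val):
            raise CohortValidationError(
                f"row {rownum}: field {field_name!r}: expected integer, got {cell!r}"
            )
        return int(val)
    return val


def _row_to_record(row: Mapping[str, str], rownum: int) -> GARecord:
    get = lambda c: (row.get(c) or "").strip()

    sex = get("sex") or None
    adl = {k: _parse_num(get(f"adl_{k}"), field_name=f"adl_{k}", rownum=rownum)
           for k in ADL_ITEM_MAX}
    adl_items = None if all(v is None for v in adl.values()) else {
        k: v for k, v in adl.items() if v is not None}
    if adl_items is not None and len(adl_items) != len(ADL_ITEM_MAX):
        missing = sorted(set(ADL_ITEM_MAX) - set(adl_items))
        raise CohortValidationError(f"row {rownum}: partial ADL (missing {missing})")

    iadl_names = _iadl_items_for(sex)
    iadl = {}
    for k in iadl_names:
        cell = get(f"iadl_{k}")
        if cell in ("", "NA"):
            continue
        if cell == _NC:
            iadl[k] = "not_capable"
        elif cell in ("independent", "dependent"):
            iadl[k] = cell
        else:
            raise CohortValidationError(f"row {rownum}: iadl_{k}={cell!r} invalid")
    iadl_items = iadl or None

    mmse_nc = get("mmse_nc") == _NC
    mmse_items = None
    if not mmse_nc:
        mmse = {k: _parse_num(get(f"mmse_{k}"), field_name=f"mmse_{k}", rownum=rownum)
                for k in MMSE_COMPONENT_MAX}
        if any(v is not None for v in mmse.values()):
            if any(v is None for v in mmse.values()):
                raise CohortValidationError(f"row {rownum}: partial MMSE components")
            mmse_items = mmse

    sgds_nc = get("sgds_nc") == _NC
    sgds_items = None
    if not sgds_nc:
        sgds = {k: _parse_num(get(f"sgds_{k}"), field_name=f"sgds_{k}", rownum=rownum,
                              integer=True) for k in SGDS_ITEMS}
        if any(v is not None for v in sgds.values()):
            if any(v is None for v in sgds.values()):
                raise CohortValidationError(f"row {rownum}: partial SGDS items")
            sgds_items = sgds

    mna_nc = get("mna_nc") == _NC
    mna_items = None
    if not mna_nc:
        mna = {k: _parse_num(get(f"mna_{k}"), field_name=f"mna_{k}", rownum=rownum)
               for k in MNA_ITEM_MAX}
        if any(v is not None for v in mna.values()):
            if any(v is None for v in mna.values()):
                raise CohortValidationError(f"row {rownum}: partial MNA items")
            mna_items = mna

    tgug_cell = get("tgug_seconds")
    tgug_nc = tgug_cell == _NC
    tgug = None if tgug_nc else _parse_num(tgug_cell, field_name="tgug_seconds", rownum=rownum)

    ev_cell = get("os_event")
    if ev_cell in ("", "NA"):
        os_event = None
    elif ev_cell in ("death", "censored"):
        os_event = ev_cell == "death"
    else:
        raise CohortValidationError(f"row {rownum}: os_event={ev_cell!r} invalid")

    rec = GARecord(
        patient_id=get("patient_id"),
        age=_parse_num(get("age"), field_name="age", rownum=rownum, integer=True),
        sex=sex,
        adl_items=adl_items,
        iadl_items=iadl_items,
        mmse_items=mmse_items,
        mmse_not_capable=mmse_nc,
        sgds_items=sgds_items,
        sgds_not_capable=sgds_nc,
        mna_items=mna_items,
        mna_not_capable=mna_nc,
        tgug_seconds=tgug,
        tgug_not_capable=tgug_nc,
        charlson_points=_parse_num(get("charlson_points"), field_name="charlson_points",
                                   rownum=rownum, integer=True),
        n_drugs=_parse_num(get("n_drugs"), field_name="n_drugs", rownum=rownum, integer=True),
        os_time=_parse_num(get("os_time"), field_name="os_time", rownum=rownum),
        os_event=os_event,
    )
    try:
        rec.validate()
    except CohortValidationError as exc:
        raise CohortValidationError(f"row {rownum}: {exc}") from exc
    return rec


def read_cohort(path, provenance: str | None = None) -> Cohort:
    """Read a cohort CSV (see the packaged column dictionary).

    Empty cells and ``NA`` are missing; ``NC`` marks not-capable responses.
    Raises :class:`CohortValidationError` naming the offending row and field
    on any type, range or uniqueness violation.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "patient_id" not in df.columns:
        raise CohortValidationError("cohort CSV lacks a patient_id column")
    records = [_row_to_record(row, rownum=i + 2)  # +2: header is line 1
               for i, row in enumerate(df.to_dict(orient="records"))]
    return Cohort(records=records, provenance=provenance or str(path))


def write_cohort(cohort: Cohort, path) -> None:
    """Write a cohort CSV such that ``read_cohort`` reproduces it field-for-field."""
    rows = [_record_to_row(r) for r in cohort]
    pd.DataFrame(rows, columns=_columns()).to_csv(path, index=False)
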