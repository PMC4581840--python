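"""The KG-7 screening questionnaire and the G-8 comparator.

The KG-7 is seven yes/no-style questions, one point per favorable answer
(total 0-7, higher = better); a score of 5 or less is screen-positive
(suspected abnormal GA).  The G-8 sums seven MNA-derived items plus an
age band (total 0-17, 0.5 steps); 14 or less is screen-positive.  Missing
items are never pro-rated: any missing response makes the total missing
and the abnormal flag indeterminate.

Instrument definitions (question text, response domains, point maps,
cut-offs) ship as JSON in ``kg7screen/data/instruments.json``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

from .cohort_model import GARecord

__all__ = [
    "Instrument",
    "InstrumentScore",
    "load_instrument",
    "score_kg7",
    "derive_kg7_responses",
    "score_g8",
    "KG7_ITEM_IDS",
]

KG7_ITEM_IDS = (
    "shower_bath",
    "ascend_stairs",
    "shopping",
    "nutrition_self_view",
    "over_3_drugs",
    "date_orientation",
    "dropped_activities",
)


@dataclass(frozen=True)
class Instrument:
    """A screening questionnaire definition."""

    name: str
    items: tuple[dict, ...]
    score_range: tuple[float, float]
    abnormal_cutoff: float  # abnormal iff total <= cutoff


@dataclass(frozen=True)
class InstrumentScore:
    """A patient's total on one screening instrument."""

    patient_id: str | None
    instrument: str
    item_points: dict[str, float | None]
    total: float | None
    abnormal: bool | None
    n_missing_items: int


@lru_cache(maxsize=None)
def _definitions() -> dict:
    with resources.files("kg7screen.data").joinpath("instruments.json").open() as fh:
        return json.load(fh)


def load_instrument(name: str) -> Instrument:
    """Load a packaged instrument definition (``"kg7"`` or ``"g8"``)."""
    try:
        raw = _definitions()[name.lower()]
    except KeyError:
        raise KeyError(f"unknown instrument {name!r}") from None
    return Instrument(
        name=raw["name"],
        items=tuple(raw["items"]),
        score_range=tuple(raw["score_range"]),
        abnormal_cutoff=raw["abnormal_rule"]["cutoff"],
    )


def score_kg7(responses: dict[str, str | None],
              patient_id: str | None = None) -> InstrumentScore:
    """Score the seven KG-7 responses.

    ``responses`` maps each KG-7 item id to its raw answer (``"yes"`` /
    ``"no"``, ``"good"`` / ``"bad"``, ``"correct"`` / ``"incorrect"``) or
    ``None`` when unanswerable.  No partial scoring: any ``None`` yields a
    missing total and an indeterminate abnormal flag.
    """
    inst = load_instrument("kg7")
    points: dict[str, float | None] = {}
    extra = set(responses) - set(KG7_ITEM_IDS)
    if extra:
        raise ValueError(f"unknown KG-7 item(s): {sorted(extra)}")
    for item in inst.items:
        iid = item["item_id"]
        resp = responses.get(iid)
        if resp is None:
            points[iid] = None
            continue
        if resp not in item["points"]:
            raise ValueError(
                f"item {iid!r}: response {resp!r} not in {sorted(item['points'])}"
            )
        points[iid] = item["points"][resp]
    n_missing = sum(1 for v in points.values() if v is None)
    if n_missing:
        total, abnormal = None, None
    else:
        total = int(sum(points.values()))
        abnormal = total <= inst.abnormal_cutoff
    return InstrumentScore(
        patient_id=patient_id,
        instrument="KG-7",
        item_points=points,
        total=total,
        abnormal=abnormal,
        n_missing_items=n_missing,
    )


def derive_kg7_responses(record: GARecord) -> dict[str, str | None]:
    """Map a GA record's item-level data onto the seven KG-7 responses.

    The mapping is deterministic: ADL bathing -> shower/bath, ADL stairs ->
    ascending stairs, IADL shopping -> shopping, MNA self-view -> nutrition
    self-view, MNA >3-prescription-drugs (falling back to the drug count
    when the MNA was not administered) -> drug question, all three MMSE-KC
    date components correct -> date orientation, SGDS dropped-activities ->
    activities question.  A not-capable instrument yields the unfavorable
    response (observed inability); a missing source yields ``None``.
    """
    r: dict[str, str | None] = {}

    if record.adl_items is None:
        r["shower_bath"] = r["ascend_stairs"] = None
    else:
        r["shower_bath"] = "yes" if record.adl_items["bathing"] == 5 else "no"
        r["ascend_stairs"] = "yes" if record.adl_items["stairs"] == 10 else "no"

    if record.iadl_items is None or "shopping" not in record.iadl_items:
        r["shopping"] = None
    else:
        r["shopping"] = "yes" if record.iadl_items["shopping"] == "independent" else "no"

    if record.mna_not_capable:
        r["nutrition_self_view"] = "bad"
    elif record.mna_items is None:
        r["nutrition_self_view"] = None
    else:
        r["nutrition_self_view"] = "good" if record.mna_items["self_view_nutrition"] == 2 else "bad"

    if record.mna_items is not None:
        r["over_3_drugs"] = "no" if record.mna_items["more_than_3_drugs"] == 1 else "yes"
    elif record.n_drugs is not None:
        r["over_3_drugs"] = "yes" if record.n_drugs > 3 else "no"
    elif record.mna_not_capable:
        r["over_3_drugs"] = "yes"
    else:
        r["over_3_drugs"] = None

    if record.mmse_not_capable:
        r["date_orientation"] = "incorrect"
    elif record.mmse_items is None:
        r["date_orientation"] = None
    else:
        r["date_orientation"] = (
            "correct" if record.mmse_items["orientation_time_date"] == 3 else "incorrect"
        )

    if record.sgds_not_capable:
        r["dropped_activities"] = "yes"
    elif record.sgds_items is None:
        r["dropped_activities"] = None
    else:
        r["dropped_activities"] = "yes" if record.sgds_items["dropped_activities"] == 1 else "no"

    return r


def score_g8(mna_items: dict[str, float] | None, age: int | None,
             patient_id: str | None = None) -> InstrumentScore:
    """Score the G-8 from the constituent MNA items and age.

    Uses the published G-8 weights: the seven MNA components carry their
    MNA point values (food-intake decline 0-2, weight loss 0-3, mobility
    0-2, neuropsychological problems 0-2, BMI 0-3, >3 drugs 0/1, self-rated
    health vs peers 0-2) and age contributes 2 (<80 y), 1 (80-85 y) or
    0 (>85 y).  Any missing component makes the total missing.
    """
    inst = load_instrument("g8")
    points: dict[str, float | None] = {}
    for item in inst.items:
        iid = item["item_id"]
        if item["source"] == "age":
            if age is None:
                points["age"] = None
            else:
                points["age"] = next(pts for lo, hi, pts in item["bands"] if lo <= age <= hi)
            continue
        val = None if mna_items is None else mna_items.get(iid)
        if val is None:
            points[iid] = None
        else:
            if val not in item["points"]:
                raise ValueError(f"G-8 item {iid!r}: value {val!r} not in {item['points']}")
            points[iid] = val
    n_missing = sum(1 for v in points.values() if v is None)
    if n_missing:
        total, abnormal = None, None
    else:
        total = float(sum(points.values()))
        abnormal = total <= inst.abnormal_cutoff
    return InstrumentScore(
        patient_id=patient_id,
        instrument="G-8",
        item_points=points,
        total=total,
        abnormal=abnormal,
        n_missing_items=n_missing,
    )
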