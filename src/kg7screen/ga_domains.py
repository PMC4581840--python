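"""Domain categorization and the abnormal-GA reference standard.

Each of the six reference domains (ADL, IADL, MMSE, SGDS, MNA, TGUG) is
categorized as intact / mild / severe from the raw instrument responses;
Charlson comorbidity is categorized descriptively (low / medium / high /
very high) and never enters the reference standard.

The reference labels are:

* ``abnormal_ga`` — deficits (mild-or-worse impairment) in at least 2 of
  the 6 domains;
* ``severe_any`` — severe impairment in at least 1 of the 6 domains
  (ADL total ≤75, IADL independent-count ≤3 for men / ≤6 for women,
  MMSE <17, SGDS ≥10, MNA <17, TGUG ≥25 s, or a not-capable response).

When some domains are unassessed, a flag is reported only if every
possible completion of the missing domains agrees on it; otherwise it is
indeterminate (``None``).
"""

from __future__ import annotations

from dataclasses import dataclass

from .cohort_model import GARecord

__all__ = [
    "REFERENCE_DOMAINS",
    "DomainStatus",
    "GAClassification",
    "categorize_domain",
    "classify_ga",
]

#: Domains entering the abnormal-GA / severe-any reference standard.
REFERENCE_DOMAINS: tuple[str, ...] = ("ADL", "IADL", "MMSE", "SGDS", "MNA", "TGUG")

ALL_DOMAINS = REFERENCE_DOMAINS + ("CHARLSON",)

CATEGORIES = ("intact", "mild", "severe", "missing")

#: Charlson comorbidity bands (descriptive only).
CHARLSON_BANDS = ("low", "medium", "high", "very_high")

#: Published categorization thresholds; overridable via the JSON config
#: (``kg7screen/data/default_config.json``, key ``thresholds``).
DEFAULT_THRESHOLDS: dict = {
    "adl_severe_max_total": 75,
    "iadl_severe_max_independent": {"male": 3, "female": 6},
    "mmse": {"severe_max": 16, "mild_max": 24},
    "sgds": {"severe_min": 10, "mild_min": 5},
    "mna": {"severe_below": 17, "intact_from": 24},
    "tgug": {"deficit_over_seconds": 20, "severe_from_seconds": 25},
    "charlson_bands": {"low": (0, 0), "medium": (1, 2), "high": (3, 4),
                       "very_high": (5, None)},
}


@dataclass(frozen=True)
class DomainStatus:
    """Ordinal impairment category of one GA domain for one patient."""

    domain: str
    category: str  # intact | mild | severe | missing
    raw_total: float | None = None
    band: str | None = None  # Charlson only

    @property
    def is_deficit(self) -> bool:
        return self.category in ("mild", "severe")


@dataclass(frozen=True)
class GAClassification:
    """Reference-standard labels derived from the six domain statuses."""

    statuses: dict[str, DomainStatus]
    n_deficits: int          # deficits among *observed* domains
    n_missing: int
    abnormal_ga: bool | None  # None = indeterminate
    severe_any: bool | None


def _status(domain: str, category: str, raw=None, band=None) -> DomainStatus:
    return DomainStatus(domain=domain, category=category, raw_total=raw, band=band)


def categorize_domain(record: GARecord, domain: str,
                      thresholds: dict | None = None) -> DomainStatus:
    """Categorize one GA domain of ``record``.

    Thresholds (severe band first, then the mild/deficit band):

    ======== ==========================================================
    ADL      total <=75 severe; any item dependency mild; else intact
    IADL     independent count <=3 (male) / <=6 (female) severe;
             >=1 dependent/not-capable item mild; else intact
    MMSE     total <=16 severe; 17-24 mild; 25-30 intact
    SGDS     total >=10 severe; 5-9 mild; <5 intact
    MNA      total <17 severe; 17-23.5 mild (at risk); >=24 intact
    TGUG     >=25 s severe; >20 s mild; <=20 s intact
    CHARLSON 0 low, 1-2 medium, 3-4 high, >=5 very high (descriptive)
    ======== ==========================================================

    An instrument-level not-capable response is categorized severe.
    Missing raw data yields category ``missing``.  Pass ``thresholds``
    (shape of :data:`DEFAULT_THRESHOLDS`) to override any band.
    """
    thr_cfg = {**DEFAULT_THRESHOLDS, **(thresholds or {})}
    d = domain.upper()
    if d == "ADL":
        total = record.adl_total
        if total is None:
            return _status(d, "missing")
        if total <= thr_cfg["adl_severe_max_total"]:
            return _status(d, "severe", total)
        from .cohort_model import ADL_ITEM_MAX
        dependent = any(record.adl_items[k] < ADL_ITEM_MAX[k] for k in record.adl_items)
        return _status(d, "mild" if dependent else "intact", total)
    if d == "IADL":
        if record.iadl_items is None or record.sex not in ("male", "female"):
            return _status(d, "missing")
        indep = record.iadl_independent_count
        thr = thr_cfg["iadl_severe_max_independent"][record.sex]
        if indep <= thr:
            return _status(d, "severe", indep)
        n_dep = len(record.iadl_items) - indep
        return _status(d, "mild" if n_dep >= 1 else "intact", indep)
    if d == "MMSE":
        if record.mmse_not_capable:
            return _status(d, "severe")
        total = record.mmse_total
        if total is None:
            return _status(d, "missing")
        if total <= thr_cfg["mmse"]["severe_max"]:
            return _status(d, "severe", total)
        return _status(d, "mild" if total <= thr_cfg["mmse"]["mild_max"] else "intact", total)
    if d == "SGDS":
        if record.sgds_not_capable:
            return _status(d, "severe")
        total = record.sgds_total
        if total is None:
            return _status(d, "missing")
        if total >= thr_cfg["sgds"]["severe_min"]:
            return _status(d, "severe", total)
        return _status(d, "mild" if total >= thr_cfg["sgds"]["mild_min"] else "intact", total)
    if d == "MNA":
        if record.mna_not_capable:
            return _status(d, "severe")
        total = record.mna_total
        if total is None:
            return _status(d, "missing")
        if total < thr_cfg["mna"]["severe_below"]:
            return _status(d, "severe", total)
        return _status(d, "mild" if total < thr_cfg["mna"]["intact_from"] else "intact", total)
    if d == "TGUG":
        if record.tgug_not_capable:
            return _status(d, "severe")
        t = record.tgug_seconds
        if t is None:
            return _status(d, "missing")
        if t >= thr_cfg["tgug"]["severe_from_seconds"]:
            return _status(d, "severe", t)
        return _status(d, "mild" if t > thr_cfg["tgug"]["deficit_over_seconds"] else "intact", t)
    if d == "CHARLSON":
        p = record.charlson_points
        if p is None:
            return _status(d, "missing")
        band = None
        for name, (lo, hi) in thr_cfg["charlson_bands"].items():
            if p >= lo and (hi is None or p <= hi):
                band = name
                break
        # category mirrors the band ordinally; never used as a reference deficit
        cat = {"low": "intact", "medium": "mild"}.get(band, "severe")
        return _status(d, cat, p, band=band)
    raise ValueError(f"unknown GA domain {domain!r}")


def classify_ga(record: GARecord,
                thresholds: dict | None = None) -> GAClassification:
    """Derive the abnormal-GA and severe-any reference labels.

    Both flags are tri-state: ``True``/``False`` when every completion of
    the missing domains agrees, ``None`` (indeterminate) otherwise.
    """
    statuses = {d: categorize_domain(record, d, thresholds) for d in REFERENCE_DOMAINS}
    cats = [s.category for s in statuses.values()]
    n_def = sum(c in ("mild", "severe") for c in cats)
    n_miss = sum(c == "missing" for c in cats)

    if n_def >= 2:
        abnormal: bool | None = True
    elif n_def + n_miss < 2:
        abnormal = False
    else:
        abnormal = None

    if any(c == "severe" for c in cats):
        severe: bool | None = True
    elif n_miss == 0:
        severe = False
    else:
        severe = None

    return GAClassification(
        statuses=statuses,
        n_deficits=n_def,
        n_missing=n_miss,
        abnormal_ga=abnormal,
        severe_any=severe,
    )
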