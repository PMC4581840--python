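"""Per-item screening value and the item-selection algorithm.

Every candidate item of a GA instrument is dichotomized (impaired response
vs not) and evaluated against its own domain's impairment categories:
sensitivity, specificity, PPV and NPV are computed from the 2x2 table of
item response vs case status.  For domains with both a mild and a severe
impairment band (MMSE, SGDS, MNA) the metrics are computed per category —
category-vs-rest, so the non-case group differs between the two analyses —
and averaged; single-band domains (ADL, IADL, TGUG) have one category,
deficit-vs-intact.

Selection within a domain proceeds in two passes: items with mean SE >90%
are candidates first; if fewer than two remain after feasibility
exclusions, the pool widens to mean SE >80%.  The two candidates with the
highest balanced accuracy ((mean SE + mean SP)/2) are selected.
Feasibility exclusions are configuration data (expert-panel judgment, not
computed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

from .cohort_model import (
    ADL_ITEM_MAX,
    Cohort,
    GARecord,
    IADL_ITEMS_FEMALE,
    MMSE_COMPONENT_MAX,
    MNA_ITEM_MAX,
    SGDS_ITEMS,
)
from .ga_domains import categorize_domain

__all__ = [
    "ItemScreeningValue",
    "SelectionResult",
    "item_screening_value",
    "screen_domain",
    "select_items",
    "candidate_items",
]

#: Impairment categories per domain (order fixed: mild before severe).
DOMAIN_CATEGORIES: dict[str, tuple[str, ...]] = {
    "ADL": ("deficit",),
    "IADL": ("deficit",),
    "TGUG": ("deficit",),
    "MMSE": ("mild", "severe"),
    "SGDS": ("mild", "severe"),
    "MNA": ("mild", "severe"),
}


@dataclass(frozen=True)
class CategoryMetrics:
    """2x2-table metrics of one item against one impairment category."""

    category: str
    se: float | None
    sp: float | None
    ppv: float | None
    npv: float | None
    n_cases: int
    n_noncases: int

    @property
    def defined(self) -> bool:
        return self.se is not None and self.sp is not None


@dataclass(frozen=True)
class ItemScreeningValue:
    """Screening value of one candidate item for its domain's impairment."""

    item_id: str
    domain: str
    per_category: tuple[CategoryMetrics, ...]
    mean_se: float | None
    mean_sp: float | None

    @property
    def balanced_accuracy(self) -> float | None:
        if self.mean_se is None or self.mean_sp is None:
            return None
        return (self.mean_se + self.mean_sp) / 2


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of the two-pass item selection within one domain."""

    domain: str
    threshold_used: float  # 0.90 or 0.80
    candidates: tuple[ItemScreeningValue, ...]  # ranked, widened pool
    selected: tuple[str, ...]
    excluded_by_feasibility: dict[str, str] = field(default_factory=dict)
    shortfall: bool = False  # fewer than the requested number selectable


# ---------------------------------------------------------------------------
# Candidate-item registry: item_id -> (domain, record -> impaired|None)
# ---------------------------------------------------------------------------

Extractor = Callable[[GARecord], "bool | None"]


def _adl_extractor(item: str) -> Extractor:
    def ex(r: GARecord):
        if r.adl_items is None:
            return None
        return r.adl_items[item] < ADL_ITEM_MAX[item]
    return ex


def _iadl_extractor(item: str) -> Extractor:
    def ex(r: GARecord):
        if r.iadl_items is None or item not in r.iadl_items:
            return None
        return r.iadl_items[item] != "independent"
    return ex


def _mmse_extractor(component: str) -> Extractor:
    def ex(r: GARecord):
        if r.mmse_items is None:
            return None
        return r.mmse_items[component] < MMSE_COMPONENT_MAX[component]
    return ex


def _mmse_orientation_time(r: GARecord):
    if r.mmse_items is None:
        return None
    got = r.mmse_items["orientation_time_date"] + r.mmse_items["orientation_time_other"]
    return got < 5


def _sgds_extractor(item: str) -> Extractor:
    def ex(r: GARecord):
        if r.sgds_items is None:
            return None
        return r.sgds_items[item] == 1
    return ex


def _mna_extractor(item: str) -> Extractor:
    def ex(r: GARecord):
        if r.mna_items is None:
            return None
        return r.mna_items[item] < MNA_ITEM_MAX[item][0]
    return ex


def _tgug(r: GARecord):
    if r.tgug_not_capable:
        return True
    if r.tgug_seconds is None:
        return None
    return r.tgug_seconds > 20


def candidate_items() -> dict[str, tuple[str, Extractor]]:
    """All registered candidate items: ``item_id -> (domain, extractor)``."""
    reg: dict[str, tuple[str, Extractor]] = {}
    for k in ADL_ITEM_MAX:
        reg[f"adl_{k}"] = ("ADL", _adl_extractor(k))
    for k in IADL_ITEMS_FEMALE:
        reg[f"iadl_{k}"] = ("IADL", _iadl_extractor(k))
    for k in MMSE_COMPONENT_MAX:
        if k.startswith("orientation_time"):
            continue
        reg[f"mmse_{k}"] = ("MMSE", _mmse_extractor(k))
    reg["mmse_orientation_time"] = ("MMSE", _mmse_orientation_time)
    for k in SGDS_ITEMS:
        reg[f"sgds_{k}"] = ("SGDS", _sgds_extractor(k))
    for k in MNA_ITEM_MAX:
        reg[f"mna_{k}"] = ("MNA", _mna_extractor(k))
    reg["tgug_over_20s"] = ("TGUG", _tgug)
    return reg


# ---------------------------------------------------------------------------
# Screening value
# ---------------------------------------------------------------------------

def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def _category_metrics(category: str, pairs: list[tuple[bool, bool]]) -> CategoryMetrics:
    """Metrics from (item_impaired, is_case) pairs."""
    tp = sum(1 for imp, case in pairs if imp and case)
    fn = sum(1 for imp, case in pairs if not imp and case)
    fp = sum(1 for imp, case in pairs if imp and not case)
    tn = sum(1 for imp, case in pairs if not imp and not case)
    return CategoryMetrics(
        category=category,
        se=_ratio(tp, tp + fn),
        sp=_ratio(tn, fp + tn),
        ppv=_ratio(tp, tp + fp),
        npv=_ratio(tn, tn + fn),
        n_cases=tp + fn,
        n_noncases=fp + tn,
    )


def item_screening_value(cohort: Cohort, item_id: str, domain: str | None = None,
                         extractor: Extractor | None = None) -> ItemScreeningValue:
    """Screening value of one item against its domain's impairment.

    Patients with a missing domain category or missing item response are
    excluded pairwise.  A category with zero cases or zero non-cases
    yields ``None`` metrics for that category (flagged, still reportable);
    the means run over the defined categories.
    """
    if extractor is None or domain is None:
        reg = candidate_items()
        if item_id not in reg:
            raise KeyError(f"unknown candidate item {item_id!r}")
        reg_domain, extractor = reg[item_id]
        domain = domain or reg_domain
    domain = domain.upper()
    categories = DOMAIN_CATEGORIES[domain]

    observed: list[tuple[bool, str]] = []
    for rec in cohort:
        imp = extractor(rec)
        status = categorize_domain(rec, domain)
        if imp is None or status.category == "missing":
            continue
        observed.append((imp, status.category))

    per_cat = []
    for c in categories:
        if c == "deficit":
            pairs = [(imp, cat in ("mild", "severe")) for imp, cat in observed]
        else:
            pairs = [(imp, cat == c) for imp, cat in observed]
        per_cat.append(_category_metrics(c, pairs))

    defined = [m for m in per_cat if m.defined]
    mean_se = sum(m.se for m in defined) / len(defined) if defined else None
    mean_sp = sum(m.sp for m in defined) / len(defined) if defined else None
    return ItemScreeningValue(
        item_id=item_id,
        domain=domain,
        per_category=tuple(per_cat),
        mean_se=mean_se,
        mean_sp=mean_sp,
    )


def screen_domain(cohort: Cohort, domain: str) -> list[ItemScreeningValue]:
    """Screening values of every registered candidate item of ``domain``."""
    domain = domain.upper()
    out = []
    for item_id, (d, ex) in candidate_items().items():
        if d == domain:
            out.append(item_screening_value(cohort, item_id, domain=d, extractor=ex))
    return out


# ---------------------------------------------------------------------------
# Selection
# ---------------------------------------------------------------------------

def select_items(values: Sequence[ItemScreeningValue],
                 feasibility_exclusions: Mapping[str, str] | None = None,
                 se_thresholds: Sequence[float] = (0.90, 0.80),
                 n_select: int = 2) -> SelectionResult:
    """Run the two-pass high-sensitivity selection within one domain.

    Pass 1 keeps items with mean SE above ``se_thresholds[0]`` (strict),
    minus feasibility exclusions; if fewer than ``n_select`` remain the
    pool widens to the next threshold.  The ``n_select`` highest
    balanced-accuracy items are selected; ties break by higher mean SE,
    then lexicographic item id.
    """
    if not values:
        raise ValueError("select_items requires at least one screening value")
    domains = {v.domain for v in values}
    if len(domains) != 1:
        raise ValueError(f"screening values span multiple domains: {sorted(domains)}")
    excl = dict(feasibility_exclusions or {})
    relevant_excl = {k: v for k, v in excl.items() if k in {v.item_id for v in values}}

    scored = [v for v in values if v.mean_se is not None and v.balanced_accuracy is not None]

    threshold_used = se_thresholds[0]
    pool: list[ItemScreeningValue] = []
    for thr in se_thresholds:
        threshold_used = thr
        pool = [v for v in scored if v.mean_se > thr and v.item_id not in excl]
        if len(pool) >= n_select:
            break

    ranked = sorted(pool, key=lambda v: (-v.balanced_accuracy, -v.mean_se, v.item_id))
    selected = tuple(v.item_id for v in ranked[:n_select])
    return SelectionResult(
        domain=domains.pop(),
        threshold_used=threshold_used,
        candidates=tuple(ranked),
        selected=selected,
        excluded_by_feasibility=relevant_excl,
        shortfall=len(selected) < n_select,
    )
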