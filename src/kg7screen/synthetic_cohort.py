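"""Synthetic GA cohorts with the statistical structure the analysis assumes.

The generator emulates a hospital GA registry: a standard-normal latent
frailty trait (shifted with age) drives every domain through a
probit-style ordinal model, so impairments co-occur across domains the
way the screening score's discrimination requires.  Domain category
thresholds are calibrated by quantiles of a large seeded latent sample,
so the configured marginal category rates (defaults: the development
registry's distribution) are matched closely by construction.  Item-level
responses are then filled in consistently with the drawn category —
always on the correct side of every categorization threshold — with
configurable item-impairment propensities (e.g. bathing and stairs carry
most ADL dependencies).  Survival is exponential with log-hazard linear
in the number of unfavorable KG-7 answers, plus independent censoring.

Every draw flows from one ``numpy`` Generator seeded from the config, so
cohorts are byte-identical under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort_model import (
    ADL_ITEM_MAX,
    Cohort,
    GARecord,
    IADL_ITEMS_FEMALE,
    IADL_ITEMS_MALE,
    MMSE_COMPONENT_MAX,
    MNA_ITEM_MAX,
    SGDS_ITEMS,
)
from .diagnostics import ScoreCrossTable
from .instruments import derive_kg7_responses, score_kg7
from .survival import SurvivalSample

__all__ = [
    "SyntheticConfig",
    "generate_cohort",
    "generate_crosstable_cohort",
    "generate_two_group_survival",
]

@dataclass
class SyntheticConfig:
    """Generator parameters; defaults emulate the development registry.

    ``marginals`` are target category rates per domain, ordered
    intact → mild → severe (severe includes instrument-level not-capable
    responses, split off by ``nc_share``).  ``loadings`` are the latent
    frailty slopes; loading 0 makes a domain independent of the trait.
    """

    n_patients: int = 1284
    seed: int = 0

    # age bands: (lo, hi, probability)
    age_bands: tuple = (
        (58, 59, 0.002),
        (60, 69, 0.136),
        (70, 79, 0.505),
        (80, 89, 0.313),
        (90, 101, 0.044),
    )
    p_male: float = 0.382
    #: latent-frailty shift per year of age from the cohort median (77 y)
    age_slope: float = 0.03

    marginals: dict = field(default_factory=lambda: {
        "adl": {"intact": 0.508, "mild": 0.206, "severe": 0.286},
        # most IADL-dependent patients have >=2 dependent items: required
        # for one item (shopping) to carry ~91% sensitivity alone
        "iadl": {"intact": 0.389, "mild": 0.079, "severe": 0.532},
        "mmse": {"intact": 0.374, "mild": 0.333, "severe": 0.294},
        "sgds": {"intact": 0.451, "mild": 0.255, "severe": 0.294},
        "mna": {"intact": 0.276, "mild": 0.346, "severe": 0.378},
        "tgug": {"intact": 0.544, "mild": 0.228, "severe": 0.228},
        "charlson": {"low": 0.305, "medium": 0.464, "high": 0.131, "very_high": 0.100},
        "drugs": {"low": 0.191, "mid": 0.172, "high": 0.637},
    })

    #: share of the severe category carried by not-capable responses
    nc_share: dict = field(default_factory=lambda: {
        "iadl": 0.02, "mmse": 0.05, "sgds": 0.456, "mna": 0.034, "tgug": 0.10,
    })

    loadings: dict = field(default_factory=lambda: {
        "adl": 2.0, "iadl": 2.0, "mmse": 2.0, "sgds": 1.6,
        "mna": 2.0, "tgug": 1.8, "charlson": 0.3, "drugs": 1.2,
    })

    #: probability that a given item carries a dependency, by category
    item_params: dict = field(default_factory=lambda: {
        "adl": {
            "mild": {"bathing": 0.90, "stairs": 0.70, "other": 0.05},
            "severe": {"bathing": 0.98, "stairs": 0.95, "other": 0.60},
        },
        "iadl": {
            "mild_choice": {"shopping": 0.448, "food_preparation": 0.416},
            "severe": {"shopping": 0.98, "food_preparation": 0.97, "other": 0.75},
        },
        "mmse_weights": {
            "attention_calculation": 0.35, "recall": 0.24,
            "orientation_place": 0.12, "orientation_time_date": 0.09,
            "orientation_time_other": 0.05, "complex_commands": 0.10,
            "language": 0.04, "registration": 0.01,
        },
        "sgds_weights": {
            "dropped_activities": 0.19, "full_of_energy": 0.21, "good_spirits": 0.16,
        },
        "mna_weights": {
            "health_comparison": 0.18, "self_view_nutrition": 0.15,
            "protein_intake": 0.12, "food_intake_decline": 0.10,
            "weight_loss": 0.09, "bmi": 0.05, "full_meals": 0.05,
            "mobility": 0.05, "neuropsych_problems": 0.05,
            "fruits_vegetables": 0.03, "fluid_intake": 0.03, "feeding_mode": 0.03,
            "mid_arm_circumference": 0.02, "calf_circumference": 0.02,
            "lives_independently": 0.015, "pressure_sores": 0.015,
        },
        "mna_stress": {"intact": 0.05, "mild": 0.75, "severe": 0.92},
    })

    missing_rates: dict = field(default_factory=lambda: {
        "adl": 0.010, "iadl": 0.010, "mmse": 0.015, "sgds": 0.010,
        "mna": 0.005, "tgug": 0.046, "n_drugs": 0.049, "charlson": 0.005,
    })

    # survival: exponential hazard, log-linear in (7 - KG-7 score)
    baseline_hazard: float = math.log(2) / (6 * 365.25)  # score-7 median ~6 y
    log_hr_per_point: float = math.log(5.1) / 7          # extreme-group HR 5.1
    censor_rate: float = 2.5e-4                          # per day
    admin_censor_days: float = 3652.5                    # 10-year cut

    calibration_n: int = 200_000

    def validate(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        for dom, cats in self.marginals.items():
            tot = sum(cats.values())
            # printed percentage tables carry rounding slack; renormalized on use
            if not math.isclose(tot, 1.0, abs_tol=0.005):
                raise ValueError(f"marginals[{dom}] sum to {tot}, not 1")
            if any(not 0 <= p <= 1 for p in cats.values()):
                raise ValueError(f"marginals[{dom}] outside [0,1]")


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _capped_multinomial(rng, total: int, caps: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Allocate ``total`` indivisible units across items with caps,
    proportionally to ``weights``; overflow redistributes."""
    caps = np.asarray(caps, dtype=int)
    w = np.asarray(weights, dtype=float)
    alloc = np.zeros(len(caps), dtype=int)
    remaining = int(total)
    if remaining > caps.sum():
        raise ValueError("loss exceeds capacity")
    while remaining > 0:
        room = caps - alloc
        ww = np.where(room > 0, w, 0.0)
        if ww.sum() == 0:
            ww = (room > 0).astype(float)
        ww = ww / ww.sum()
        draw = rng.multinomial(remaining, ww)
        take = np.minimum(draw, room)
        alloc += take
        remaining -= int(take.sum())
    return alloc


def _draw_ages(rng, n: int, bands) -> np.ndarray:
    probs = np.array([b[2] for b in bands], dtype=float)
    probs = probs / probs.sum()
    idx = rng.choice(len(bands), size=n, p=probs)
    lo = np.array([bands[i][0] for i in idx])
    hi = np.array([bands[i][1] for i in idx])
    return rng.integers(lo, hi + 1)


def _calibrate_thresholds(cfg: SyntheticConfig, seed: int) -> dict[str, np.ndarray]:
    """Category thresholds per domain from quantiles of a latent sample."""
    rng = np.random.default_rng(seed)
    n = cfg.calibration_n
    ages = _draw_ages(rng, n, cfg.age_bands)
    frailty = cfg.age_slope * (ages - 77) + rng.standard_normal(n)
    thresholds: dict[str, np.ndarray] = {}
    for dom, cats in cfg.marginals.items():
        lam = cfg.loadings.get(dom, 0.0)
        u = lam * frailty + rng.standard_normal(n)
        probs = np.array(list(cats.values()), dtype=float)
        probs = probs / probs.sum()
        cum = np.cumsum(probs)[:-1]
        thresholds[dom] = np.quantile(u, cum)
    return thresholds


# ---------------------------------------------------------------------------
# per-domain item fills (each must land on the intended side of every
# categorization threshold: the generator->classifier closure invariant)
# ---------------------------------------------------------------------------

def _fill_adl(rng, category: str, params) -> dict[str, float]:
    items = dict(ADL_ITEM_MAX)
    if category == "intact":
        return {k: float(v) for k, v in items.items()}
    p = params[category]
    names = list(items)
    chosen = [k for k in names
              if rng.random() < p.get(k, p["other"])]
    priority = [k for k in ("bathing", "stairs") if k in chosen]
    rest = [k for k in chosen if k not in priority]
    rng.shuffle(rest)
    chosen = priority + rest

    if category == "mild":
        # total must stay in (75, 100): at most 20 points lost, >=1 item hit
        if not chosen:
            chosen = ["bathing"]
        while 5 * len(chosen) > 20:
            chosen.pop()
        loss = {k: 5 for k in chosen}
        budget = 20 - sum(loss.values())
        for k in chosen:
            extra_cap = items[k] - loss[k]
            if extra_cap >= 5 and budget >= 5 and rng.random() < 0.3:
                loss[k] += 5
                budget -= 5
    else:  # severe: total <= 75
        in_low = rng.random() < 0.776  # registry: most severe totals are <=50
        target = int(rng.integers(0, 11)) * 5 if in_low else 55 + int(rng.integers(0, 5)) * 5
        total_loss = 100 - target
        if 5 * len(chosen) > total_loss:
            keep = max(1, total_loss // 5)
            chosen = chosen[:keep]
        loss = {k: 5 for k in chosen}
        budget = total_loss - sum(loss.values())
        order = list(chosen) + [k for k in names if k not in chosen]
        while budget > 0:
            progressed = False
            for k in order:
                cap = items[k] - loss.get(k, 0)
                if cap >= 5 and budget >= 5:
                    loss[k] = loss.get(k, 0) + 5
                    budget -= 5
                    progressed = True
                if budget == 0:
                    break
            if not progressed:
                break
    return {k: float(items[k] - loss.get(k, 0)) for k in names}


def _fill_iadl(rng, category: str, sex: str, params, nc: bool) -> dict[str, str]:
    names = list(IADL_ITEMS_MALE if sex == "male" else IADL_ITEMS_FEMALE)
    if nc:
        return {k: "not_capable" for k in names}
    if category == "intact":
        return {k: "independent" for k in names}
    if category == "mild":  # exactly one dependent item
        choice_p = {k: v for k, v in params["mild_choice"].items() if k in names}
        rest = [k for k in names if k not in choice_p]
        p_rest = max(0.0, 1 - sum(choice_p.values())) / len(rest)
        keys = list(choice_p) + rest
        probs = np.array(list(choice_p.values()) + [p_rest] * len(rest))
        probs = probs / probs.sum()
        dep = keys[rng.choice(len(keys), p=probs)]
        return {k: "dependent" if k == dep else "independent" for k in names}
    # severe: >=2 dependent items
    p = params["severe"]
    dep = {k for k in names if rng.random() < p.get(k, p["other"])}
    pool = [k for k in names if k not in dep]
    rng.shuffle(pool)
    while len(dep) < 2:
        dep.add(pool.pop())
    return {k: "dependent" if k in dep else "independent" for k in names}


_TOTAL_BANDS = {  # inclusive integer bands for MMSE / SGDS totals
    "mmse": {"intact": (25, 30), "mild": (17, 24), "severe": (0, 16)},
    "sgds": {"intact": (0, 4), "mild": (5, 9), "severe": (10, 15)},
}


def _fill_mmse(rng, category: str, weights) -> dict[str, float]:
    lo, hi = _TOTAL_BANDS["mmse"][category]
    total = int(rng.integers(lo, hi + 1))
    names = list(MMSE_COMPONENT_MAX)
    caps = np.array([MMSE_COMPONENT_MAX[k] for k in names])
    w = np.array([weights[k] for k in names])
    loss = _capped_multinomial(rng, 30 - total, caps, w)
    return {k: float(c - l) for k, c, l in zip(names, caps, loss)}


def _fill_sgds(rng, category: str, weights) -> dict[str, int]:
    lo, hi = _TOTAL_BANDS["sgds"][category]
    total = int(rng.integers(lo, hi + 1))
    names = list(SGDS_ITEMS)
    base = (1 - sum(weights.values())) / (len(names) - len(weights))
    w = np.array([weights.get(k, base) for k in names])
    pts = _capped_multinomial(rng, total, np.ones(len(names), dtype=int), w)
    return {k: int(v) for k, v in zip(names, pts)}


_MNA_HALF_STEP = ("protein_intake", "fluid_intake", "mid_arm_circumference")


def _fill_mna(rng, category: str, params, over_3_drugs: bool) -> dict[str, float]:
    """Fill MNA items to an exact band-consistent total.

    The >3-prescription-drugs item is pinned to the drug count; the
    psychological-stress item moves only in steps of 2; a 0.5 remainder
    goes to one of the half-step items; everything else is integer
    allocation under per-item caps.
    """
    if category == "intact":
        lo, hi = 24.0, 30.0
    elif category == "mild":
        lo, hi = 17.0, 23.5
    else:
        lo, hi = 0.0, 16.5
    drug_loss = 1 if over_3_drugs else 0
    steps = int((hi - lo) / 0.5)
    total = lo + 0.5 * int(rng.integers(0, steps + 1))
    total = min(total, 30.0 - drug_loss)

    loss = {"more_than_3_drugs": drug_loss}
    budget = 30.0 - total - drug_loss  # multiple of 0.5, >= 0

    if budget % 1:  # hand the half point to a half-step item
        k = _MNA_HALF_STEP[int(rng.integers(0, len(_MNA_HALF_STEP)))]
        loss[k] = 0.5
        budget -= 0.5

    stress = rng.random() < params["mna_stress"][category]
    if budget > 25:  # near-total loss is unreachable without the stress item
        stress = True
    if stress and budget >= 2:
        loss["psych_stress"] = 2
        budget -= 2

    names = [k for k in MNA_ITEM_MAX if k not in ("more_than_3_drugs", "psych_stress")]
    caps = np.array([int(MNA_ITEM_MAX[k][0] - loss.get(k, 0)) for k in names])
    budget = min(budget, float(caps.sum()))  # clamps only the deepest severe totals
    w = np.array([params["mna_weights"][k] for k in names])
    alloc = _capped_multinomial(rng, int(budget), caps, w)
    for k, a in zip(names, alloc):
        loss[k] = loss.get(k, 0) + int(a)
    return {k: float(MNA_ITEM_MAX[k][0] - loss.get(k, 0)) for k in MNA_ITEM_MAX}


def _fill_tgug(rng, category: str):
    if category == "intact":
        return float(np.round(rng.uniform(8.0, 20.0), 1))
    if category == "mild":
        return float(np.round(rng.uniform(20.6, 24.9), 1))
    return float(np.round(rng.uniform(25.0, 60.0), 1))


_CHARLSON_POINTS = {"low": (0, 0), "medium": (1, 2), "high": (3, 4), "very_high": (5, 8)}
_DRUG_BANDS = {"low": (0, 2), "mid": (3, 4), "high": (5, 12)}


# ---------------------------------------------------------------------------
# main generator
# ---------------------------------------------------------------------------

def generate_cohort(config: SyntheticConfig | None = None,
                    ) -> tuple[Cohort, dict]:
    """Generate a synthetic GA cohort plus a ground-truth sidecar.

    The sidecar records each patient's latent frailty, intended domain
    categories, pre-missingness KG-7 total and the generating parameters.
    """
    cfg = config or SyntheticConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    thresholds = _calibrate_thresholds(cfg, seed=cfg.seed + 10_007)
    n = cfg.n_patients

    ages = _draw_ages(rng, n, cfg.age_bands)
    sexes = np.where(rng.random(n) < cfg.p_male, "male", "female")
    frailty = cfg.age_slope * (ages - 77) + rng.standard_normal(n)

    cat_names = {dom: list(cats) for dom, cats in cfg.marginals.items()}
    categories: dict[str, list[str]] = {}
    for dom in cfg.marginals:
        lam = cfg.loadings.get(dom, 0.0)
        u = lam * frailty + rng.standard_normal(n)
        idx = np.searchsorted(thresholds[dom], u)
        categories[dom] = [cat_names[dom][i] for i in idx]

    records: list[GARecord] = []
    truth_patients: list[dict] = []
    ip = cfg.item_params
    for i in range(n):
        pid = f"SYN{i:05d}"
        sex = str(sexes[i])
        cat = {dom: categories[dom][i] for dom in cfg.marginals}

        nc = {d: cat[d] == "severe" and rng.random() < cfg.nc_share.get(d, 0.0)
              for d in ("iadl", "mmse", "sgds", "mna", "tgug")}

        drug_band = cat["drugs"]
        lo, hi = _DRUG_BANDS[drug_band]
        n_drugs = int(rng.integers(lo, hi + 1))

        adl_items = _fill_adl(rng, cat["adl"], ip["adl"])
        iadl_items = _fill_iadl(rng, cat["iadl"], sex, ip["iadl"], nc["iadl"])
        mmse_items = None if nc["mmse"] else _fill_mmse(rng, cat["mmse"], ip["mmse_weights"])
        sgds_items = None if nc["sgds"] else _fill_sgds(rng, cat["sgds"], ip["sgds_weights"])
        mna_items = None if nc["mna"] else _fill_mna(rng, cat["mna"], ip, n_drugs > 3)
        tgug_nc = nc["tgug"]
        tgug = None if tgug_nc else _fill_tgug(rng, cat["tgug"])

        clo, chi = _CHARLSON_POINTS[cat["charlson"]]
        charlson = int(rng.integers(clo, chi + 1))

        rec = GARecord(
            patient_id=pid, age=int(ages[i]), sex=sex,
            adl_items=adl_items, iadl_items=iadl_items,
            mmse_items=mmse_items, mmse_not_capable=nc["mmse"],
            sgds_items=sgds_items, sgds_not_capable=nc["sgds"],
            mna_items=mna_items, mna_not_capable=nc["mna"],
            tgug_seconds=tgug, tgug_not_capable=tgug_nc,
            charlson_points=charlson, n_drugs=n_drugs,
        )

        kg7 = score_kg7(derive_kg7_responses(rec), patient_id=pid)
        hazard = cfg.baseline_hazard * math.exp(cfg.log_hr_per_point * (7 - kg7.total))
        t_event = rng.exponential(1.0 / hazard)
        t_cens = min(rng.exponential(1.0 / cfg.censor_rate), cfg.admin_censor_days)
        rec.os_time = float(np.round(min(t_event, t_cens), 1))
        rec.os_event = bool(t_event <= t_cens)

        # independent missingness (unassessed instruments), after truth is fixed
        mr = cfg.missing_rates
        if rng.random() < mr.get("adl", 0):
            rec.adl_items = None
        if rng.random() < mr.get("iadl", 0):
            rec.iadl_items = None
        if rng.random() < mr.get("mmse", 0):
            rec.mmse_items, rec.mmse_not_capable = None, False
        if rng.random() < mr.get("sgds", 0):
            rec.sgds_items, rec.sgds_not_capable = None, False
        if rng.random() < mr.get("mna", 0):
            rec.mna_items, rec.mna_not_capable = None, False
        if rng.random() < mr.get("tgug", 0):
            rec.tgug_seconds, rec.tgug_not_capable = None, False
        if rng.random() < mr.get("n_drugs", 0):
            rec.n_drugs = None
        if rng.random() < mr.get("charlson", 0):
            rec.charlson_points = None

        rec.validate()
        records.append(rec)
        truth_patients.append({
            "patient_id": pid,
            "frailty": float(frailty[i]),
            "categories": cat,
            "not_capable": {k: bool(v) for k, v in nc.items()},
            "kg7_true": int(kg7.total),
        })

    sidecar = {
        "params": {
            "seed": cfg.seed,
            "n_patients": cfg.n_patients,
            "loadings": dict(cfg.loadings),
            "marginals": {d: dict(c) for d, c in cfg.marginals.items()},
            "baseline_hazard": cfg.baseline_hazard,
            "log_hr_per_point": cfg.log_hr_per_point,
            "censor_rate": cfg.censor_rate,
        },
        "patients": truth_patients,
    }
    return Cohort(records=records, provenance=f"synthetic(seed={cfg.seed})"), sidecar


def generate_crosstable_cohort(table: ScoreCrossTable, seed: int = 0) -> pd.DataFrame:
    """Expand a score-by-status cross-table into patient-level rows.

    Returns a shuffled DataFrame with columns ``patient_id``, ``score``
    and ``reference`` whose cross-table reproduces ``table`` exactly.
    """
    rows = []
    for lv, n_case, n_ctrl in zip(table.levels, table.cases, table.controls):
        rows += [(lv, True)] * n_case + [(lv, False)] * n_ctrl
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(rows))
    return pd.DataFrame(
        {
            "patient_id": [f"P{i:05d}" for i in range(len(rows))],
            "score": [rows[j][0] for j in order],
            "reference": [rows[j][1] for j in order],
        }
    )


def generate_two_group_survival(n_per_arm: int, hr: float,
                                baseline_rate: float = 1e-3,
                                censor_rate: float = 8e-4,
                                seed: int = 0) -> SurvivalSample:
    """Two-arm exponential survival data with true hazard ratio ``hr``.

    Arm 1 has hazard ``hr * baseline_rate``; censoring is independent
    exponential, identical in both arms.
    """
    rng = np.random.default_rng(seed)
    group = np.repeat([0, 1], n_per_arm)
    rate = baseline_rate * np.where(group == 1, hr, 1.0)
    t_event = rng.exponential(1.0 / rate)
    t_cens = rng.exponential(1.0 / censor_rate, size=2 * n_per_arm)
    return SurvivalSample(
        times=np.minimum(t_event, t_cens),
        events=t_event <= t_cens,
        groups=group,
    )
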