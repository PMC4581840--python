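"""Diagnostic-accuracy evaluation of an ordinal screening score.

Everything derives from a :class:`ScoreCrossTable` — the counts of
reference-positive (cases, e.g. abnormal GA) and reference-negative
patients at each score level.  A screen is *positive* at ``score <=
cutoff`` (low score = at risk) for both the KG-7 and the G-8.

Provided analyses: confusion tables at a cut-off; sensitivity,
specificity, PPV and NPV with Wald 95% confidence intervals; the
screen-normal fraction (patients who would forgo full GA in a two-step
workflow); the empirical Mann-Whitney AUC with a Hanley-McNeil interval;
and constrained cut-off selection (Youden's J maximized subject to a
sensitivity floor).

The score-by-GA-status cross-table of the KG-7 development cohort ships
as a packaged fixture (:func:`development_crosstable`).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "ScoreCrossTable",
    "ConfusionTable",
    "MetricWithCI",
    "DiagnosticMetrics",
    "AUCResult",
    "CutoffResult",
    "cross_table",
    "confusion_at_cutoff",
    "diagnostic_metrics",
    "empirical_auc",
    "select_cutoff",
    "development_crosstable",
]

Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class ScoreCrossTable:
    """Counts of cases and controls at each ordered score level."""

    levels: tuple[int, ...]
    cases: tuple[int, ...]     # reference-positive per level
    controls: tuple[int, ...]  # reference-negative per level
    n_dropped: int = 0         # patients excluded (missing score/reference)

    def __post_init__(self) -> None:
        if not (len(self.levels) == len(self.cases) == len(self.controls)):
            raise ValueError("levels, cases and controls must align")
        if list(self.levels) != sorted(self.levels):
            raise ValueError("score levels must be ascending")
        if any(c < 0 for c in self.cases + self.controls):
            raise ValueError("counts must be nonnegative")

    @property
    def n_cases(self) -> int:
        return int(sum(self.cases))

    @property
    def n_controls(self) -> int:
        return int(sum(self.controls))

    @property
    def n_total(self) -> int:
        return self.n_cases + self.n_controls

    @property
    def prevalence(self) -> float:
        return self.n_cases / self.n_total


@dataclass(frozen=True)
class ConfusionTable:
    """2x2 table at one cut-off; positive screen = score <= cutoff."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricWithCI:
    """A proportion with its Wald 95% interval (None when undefined)."""

    value: float | None
    lower: float | None = None
    upper: float | None = None


@dataclass(frozen=True)
class DiagnosticMetrics:
    sensitivity: MetricWithCI
    specificity: MetricWithCI
    ppv: MetricWithCI
    npv: MetricWithCI
    balanced_accuracy: float | None
    screen_normal_fraction: float | None


@dataclass(frozen=True)
class AUCResult:
    auc: float
    lower: float
    upper: float
    method: str = "Mann-Whitney / Hanley-McNeil"


@dataclass(frozen=True)
class CutoffResult:
    cutoff: int
    youden_j: float
    sensitivity: float
    specificity: float
    constraint_met: bool
    roc_points: tuple[tuple[float, float], ...]  # (FPR, TPR), ascending


# ---------------------------------------------------------------------------


def cross_table(scores: Mapping[str, float | None],
                reference: Mapping[str, bool | None]) -> ScoreCrossTable:
    """Tabulate per-patient scores by reference status (complete-case).

    Patients with a missing score, a missing/indeterminate reference, or
    present in only one of the two mappings are dropped; the drop count is
    recorded on the result.
    """
    shared = set(scores) & set(reference)
    if not shared:
        raise ValueError("scores and reference share no patients")
    kept: list[tuple[int, bool]] = []
    n_dropped = len(set(scores) | set(reference)) - len(shared)
    for pid in shared:
        s, ref = scores[pid], reference[pid]
        if s is None or ref is None:
            n_dropped += 1
            continue
        kept.append((int(s), bool(ref)))
    if not kept:
        raise ValueError("no patient has both a score and a determinate reference")
    levels = sorted({s for s, _ in kept})
    cases = [sum(1 for s, r in kept if s == lv and r) for lv in levels]
    controls = [sum(1 for s, r in kept if s == lv and not r) for lv in levels]
    return ScoreCrossTable(tuple(levels), tuple(cases), tuple(controls), n_dropped)


def confusion_at_cutoff(table: ScoreCrossTable, cutoff: int) -> ConfusionTable:
    """2x2 confusion table with positive screen defined as score <= cutoff."""
    tp = sum(c for lv, c in zip(table.levels, table.cases) if lv <= cutoff)
    fp = sum(c for lv, c in zip(table.levels, table.controls) if lv <= cutoff)
    return ConfusionTable(tp=tp, fp=fp, fn=table.n_cases - tp, tn=table.n_controls - fp)


def _wald(num: int, den: int) -> MetricWithCI:
    if den == 0:
        return MetricWithCI(None)
    p = num / den
    half = Z95 * math.sqrt(p * (1 - p) / den)
    return MetricWithCI(p, max(0.0, p - half), min(1.0, p + half))


def diagnostic_metrics(ct: ConfusionTable) -> DiagnosticMetrics:
    """Point estimates and Wald 95% CIs for SE/SP/PPV/NPV.

    A zero denominator yields an undefined metric (``value=None``), never
    an exception.  The screen-normal fraction is (FN+TN)/total.
    """
    se = _wald(ct.tp, ct.tp + ct.fn)
    sp = _wald(ct.tn, ct.fp + ct.tn)
    ppv = _wald(ct.tp, ct.tp + ct.fp)
    npv = _wald(ct.tn, ct.tn + ct.fn)
    ba = None
    if se.value is not None and sp.value is not None:
        ba = (se.value + sp.value) / 2
    snf = (ct.fn + ct.tn) / ct.total if ct.total else None
    return DiagnosticMetrics(se, sp, ppv, npv, ba, snf)


def empirical_auc(table: ScoreCrossTable) -> AUCResult:
    """Mann-Whitney AUC: P(random case scores lower than random control),
    ties counted one half; Hanley-McNeil 95% interval.

    Low scores flag risk, so discrimination means cases sit *below*
    controls on the score scale.
    """
    na, nn = table.n_cases, table.n_controls
    if na == 0 or nn == 0:
        raise ValueError("AUC undefined: need at least one case and one control")
    cases = np.asarray(table.cases, dtype=float)
    controls = np.asarray(table.controls, dtype=float)
    # pairs where the case level is strictly below the control level
    cum_cases = np.cumsum(cases)  # cases at levels <= i
    wins = float(np.sum(controls[1:] * cum_cases[:-1]))
    ties = 0.5 * float(np.sum(cases * controls))
    auc = (wins + ties) / (na * nn)

    q1 = auc / (2 - auc)
    q2 = 2 * auc * auc / (1 + auc)
    var = (auc * (1 - auc) + (na - 1) * (q1 - auc * auc)
           + (nn - 1) * (q2 - auc * auc)) / (na * nn)
    half = Z95 * math.sqrt(max(var, 0.0))
    return AUCResult(auc=auc, lower=max(0.0, auc - half), upper=min(1.0, auc + half))


def roc_points(table: ScoreCrossTable) -> tuple[tuple[float, float], ...]:
    """ROC coordinates (FPR, TPR) for thresholds 'score <= level', plus (0,0)."""
    na, nn = table.n_cases, table.n_controls
    pts = [(0.0, 0.0)]
    tp = fp = 0
    for lv, c, d in zip(table.levels, table.cases, table.controls):
        tp += c
        fp += d
        pts.append((fp / nn, tp / na))
    return tuple(pts)


def select_cutoff(table: ScoreCrossTable, min_sensitivity: float) -> CutoffResult:
    """Pick the cut-off maximizing Youden's J subject to SE >= min_sensitivity.

    Ties break toward the lower cut-off.  If no cut-off reaches the
    sensitivity floor the unconstrained Youden maximizer is returned with
    ``constraint_met=False``.
    """
    if not 0 <= min_sensitivity <= 1:
        raise ValueError("min_sensitivity must be in [0, 1]")
    rows = []
    for lv in table.levels:
        ct = confusion_at_cutoff(table, lv)
        se = ct.tp / (ct.tp + ct.fn)
        sp = ct.tn / (ct.fp + ct.tn)
        rows.append((lv, se, sp, se + sp - 1))
    eligible = [r for r in rows if r[1] >= min_sensitivity]
    constraint_met = bool(eligible)
    pool = eligible if eligible else rows
    best = max(pool, key=lambda r: (r[3], -r[0]))
    return CutoffResult(
        cutoff=int(best[0]),
        youden_j=best[3],
        sensitivity=best[1],
        specificity=best[2],
        constraint_met=constraint_met,
        roc_points=roc_points(table),
    )


def development_crosstable() -> ScoreCrossTable:
    """The packaged KG-7 development-cohort score-by-GA-status cross-table."""
    with resources.files("kg7screen.data").joinpath(
            "development_crosstable.json").open() as fh:
        raw = json.load(fh)
    return ScoreCrossTable(
        levels=tuple(raw["levels"]),
        cases=tuple(raw["abnormal_ga"]),
        controls=tuple(raw["normal_ga"]),
    )
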