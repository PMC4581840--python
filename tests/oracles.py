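"""Independent brute-force oracles used by the test suite.

Everything here recomputes quantities from first principles (pairwise
enumeration, exhaustive completion, naive 2x2 counting) without calling
the package's own diagnostic code paths.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def expand_table(levels, cases, controls):
    """Patient-level (score, is_case) pairs from a cross-table."""
    rows = []
    for lv, a, b in zip(levels, cases, controls):
        rows += [(lv, True)] * a + [(lv, False)] * b
    return rows


def brute_confusion(rows, cutoff):
    tp = sum(1 for s, c in rows if c and s <= cutoff)
    fn = sum(1 for s, c in rows if c and s > cutoff)
    fp = sum(1 for s, c in rows if not c and s <= cutoff)
    tn = sum(1 for s, c in rows if not c and s > cutoff)
    return tp, fp, fn, tn


def brute_auc(rows):
    """Pairwise Mann-Whitney AUC (case below control; ties half)."""
    case_scores = [s for s, c in rows if c]
    ctrl_scores = [s for s, c in rows if not c]
    num = 0.0
    for a in case_scores:
        for b in ctrl_scores:
            if a < b:
                num += 1.0
            elif a == b:
                num += 0.5
    return num / (len(case_scores) * len(ctrl_scores))


def brute_best_cutoff(rows, levels, min_sensitivity):
    """Constrained Youden maximizer by direct sweep; ties -> lower cutoff."""
    best = None
    for lv in sorted(levels):
        tp, fp, fn, tn = brute_confusion(rows, lv)
        se = tp / (tp + fn)
        sp = tn / (fp + tn)
        j = se + sp - 1
        if se >= min_sensitivity and (best is None or j > best[1] + 1e-12):
            best = (lv, j)
    return None if best is None else best[0]


def brute_select(values, exclusions, thresholds=(0.90, 0.80), n=2):
    """Re-rank screening values by (SE+SP)/2 over the widened pool."""
    for thr in thresholds:
        pool = [v for v in values
                if v.mean_se is not None and v.mean_se > thr
                and v.item_id not in exclusions]
        if len(pool) >= n:
            break
    ranked = sorted(pool, key=lambda v: (-(v.mean_se + v.mean_sp) / 2,
                                         -v.mean_se, v.item_id))
    return tuple(v.item_id for v in ranked[:n])


def brute_ga_flags(pattern):
    """Tri-state (abnormal, severe_any) by enumerating every completion
    of the missing domains; ``pattern`` is a tuple over
    {'intact','mild','severe','missing'}."""
    options = {
        "intact": ["intact"], "mild": ["mild"], "severe": ["severe"],
        "missing": ["intact", "mild", "severe"],
    }
    abnormals, severes = set(), set()
    for comp in itertools.product(*(options[c] for c in pattern)):
        n_def = sum(c in ("mild", "severe") for c in comp)
        abnormals.add(n_def >= 2)
        severes.add(any(c == "severe" for c in comp))
    tri = lambda s: s.pop() if len(s) == 1 else None
    return tri(abnormals), tri(severes)


def brute_cox_loglik(beta, times, events, x):
    """Breslow partial log-likelihood by direct risk-set summation."""
    ll = 0.0
    event_times = sorted({t for t, e in zip(times, events) if e})
    for t in event_times:
        risk = [i for i in range(len(times)) if times[i] >= t]
        dead = [i for i in range(len(times)) if times[i] == t and events[i]]
        denom = sum(math.exp(beta * x[i]) for i in risk)
        for i in dead:
            ll += beta * x[i] - math.log(denom)
    return ll
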