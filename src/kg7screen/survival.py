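"""Overall-survival analysis by screening-score group.

Kaplan-Meier product-limit curves (with Greenwood variance) and the
log-rank test are computed through ``lifelines``; the Cox
proportional-hazards fit is a partial-likelihood Newton maximization
implemented here with Breslow handling of tied event times, reporting the
hazard ratio with a Wald 95% interval on the log scale.  Monotone
likelihoods (complete separation) are flagged, not raised.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from scipy import stats

__all__ = [
    "SurvivalSample",
    "KMCurve",
    "LogrankResult",
    "CoxFit",
    "km_estimate",
    "logrank_test",
    "cox_fit",
]


@dataclass(frozen=True)
class SurvivalSample:
    """Right-censored survival data, optionally grouped."""

    times: np.ndarray   # follow-up, days
    events: np.ndarray  # True = death observed
    groups: np.ndarray | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        e = np.asarray(self.events, dtype=bool)
        if t.ndim != 1 or e.shape != t.shape:
            raise ValueError("times and events must be aligned 1-D arrays")
        if not np.all(np.isfinite(t)) or np.any(t < 0):
            raise ValueError("times must be finite and nonnegative")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "events", e)
        if self.groups is not None:
            g = np.asarray(self.groups)
            if g.shape != t.shape:
                raise ValueError("groups must align with times")
            object.__setattr__(self, "groups", g)

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class KMCurve:
    """Product-limit estimate at the observed event times."""

    event_times: np.ndarray
    survival: np.ndarray       # S(t) just after each event time
    at_risk: np.ndarray
    n_events: np.ndarray
    greenwood_var: np.ndarray  # Var[S(t)] by Greenwood's formula
    degenerate: bool = False   # no events observed

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass(frozen=True)
class LogrankResult:
    statistic: float
    df: int
    p_value: float


@dataclass(frozen=True)
class CoxFit:
    coef: float
    se: float
    hr: float
    hr_lower: float
    hr_upper: float
    z: float
    p_value: float
    log_likelihood: float
    n_iter: int
    converged: bool
    ties: str = "breslow"


def km_estimate(sample: SurvivalSample) -> KMCurve:
    """Kaplan-Meier product-limit estimator.

    At tied times, deaths are processed before censorings (the standard
    events-first convention).  With no events the curve is flat at 1 and
    flagged degenerate.
    """
    if len(sample) == 0:
        raise ValueError("km_estimate requires at least one subject")
    kmf = KaplanMeierFitter()
    kmf.fit(sample.times, sample.events)
    tbl = kmf.event_table
    ev = tbl[tbl["observed"] > 0]
    if len(ev) == 0:
        return KMCurve(
            event_times=np.array([]), survival=np.array([]),
            at_risk=np.array([]), n_events=np.array([]),
            greenwood_var=np.array([]), degenerate=True,
        )
    times = ev.index.to_numpy(dtype=float)
    d = ev["observed"].to_numpy(dtype=float)
    n = ev["at_risk"].to_numpy(dtype=float)
    surv = np.array([kmf.predict(t) for t in times], dtype=float)
    greenwood = surv**2 * np.cumsum(d / (n * (n - d)))
    return KMCurve(
        event_times=times, survival=surv, at_risk=n.astype(int),
        n_events=d.astype(int), greenwood_var=greenwood,
    )


def logrank_test(sample: SurvivalSample) -> LogrankResult:
    """k-group log-rank test (observed minus expected chi-squared, df=k-1)."""
    if sample.groups is None:
        raise ValueError("logrank_test requires group labels")
    labels, counts = np.unique(sample.groups, return_counts=True)
    if len(labels) < 2:
        raise ValueError("logrank_test requires at least 2 nonempty groups")
    res = multivariate_logrank_test(sample.times, sample.groups, sample.events)
    return LogrankResult(
        statistic=float(res.test_statistic),
        df=int(len(labels) - 1),
        p_value=float(res.p_value),
    )


def _breslow_loglik(beta: float, times, events, x):
    """Breslow partial log-likelihood and derivatives for one covariate."""
    order = np.argsort(-times, kind="stable")  # descending time
    t, e, xv = times[order], events[order], x[order]
    eta = beta * xv
    w = np.exp(eta)
    # running risk-set sums over subjects with time >= current
    s0 = np.cumsum(w)
    s1 = np.cumsum(w * xv)
    s2 = np.cumsum(w * xv * xv)
    ll = dll = d2ll = 0.0
    i = 0
    n = len(t)
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        # risk set for this time = subjects with index < j (time >= t[i])
        d = e[i:j].sum()
        if d > 0:
            S0, S1, S2 = s0[j - 1], s1[j - 1], s2[j - 1]
            xsum = (xv[i:j] * e[i:j]).sum()
            ll += beta * xsum - d * np.log(S0)
            dll += xsum - d * S1 / S0
            d2ll -= d * (S2 / S0 - (S1 / S0) ** 2)
        i = j
    return ll, dll, d2ll


def cox_fit(sample: SurvivalSample, covariate: Sequence[float],
            max_iter: int = 50, tol: float = 1e-9) -> CoxFit:
    """Single-covariate Cox proportional-hazards fit.

    Newton maximization of the Breslow partial likelihood with
    step-halving; Wald 95% CI on the log-hazard scale.  A monotone
    likelihood (complete separation of the covariate) returns
    ``converged=False`` instead of raising.
    """
    x = np.asarray(covariate, dtype=float)
    if x.shape != sample.times.shape:
        raise ValueError("covariate must align with the sample")
    if not sample.events.any():
        raise ValueError("cox_fit requires at least one event")
    if np.ptp(x) == 0:
        raise ValueError("covariate is constant")

    beta = 0.0
    ll, dll, d2ll = _breslow_loglik(beta, sample.times, sample.events, x)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        if d2ll >= 0:  # flat/degenerate curvature
            break
        step = -dll / d2ll
        # step-halving to guarantee ascent
        new_beta = beta + step
        new = _breslow_loglik(new_beta, sample.times, sample.events, x)
        halvings = 0
        while new[0] < ll and halvings < 30:
            step /= 2
            new_beta = beta + step
            new = _breslow_loglik(new_beta, sample.times, sample.events, x)
            halvings += 1
        beta, (ll, dll, d2ll) = new_beta, new
        if abs(step) < tol or abs(dll) < tol:
            converged = True
            break
    se = float(np.sqrt(-1.0 / d2ll)) if d2ll < 0 else float("inf")
    # monotone likelihood (complete separation): the estimate drifts to
    # absurd log-hazard values with vanishing curvature
    if abs(beta) > 20 or not np.isfinite(se) or se > 100:
        converged = False
    z = beta / se if np.isfinite(se) and se > 0 else float("nan")
    p = float(2 * stats.norm.sf(abs(z))) if np.isfinite(z) else float("nan")
    half = 1.959963984540054 * se
    with np.errstate(over="ignore"):  # diverged fits overflow to inf cleanly
        hr, hr_lo, hr_hi = np.exp([beta, beta - half, beta + half])
    return CoxFit(
        coef=float(beta),
        se=se,
        hr=float(hr),
        hr_lower=float(hr_lo),
        hr_upper=float(hr_hi),
        z=float(z),
        p_value=p,
        log_likelihood=float(ll),
        n_iter=it,
        converged=converged,
    )
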