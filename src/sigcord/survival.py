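"""Survival estimation and discrimination.

Kaplan-Meier product-limit curves and log-rank tests are computed with
lifelines. The hazard ratio of a single binary covariate is estimated by
Newton iteration on the Cox partial likelihood with Breslow handling of
tied event times (material here, since follow-up is recorded in months),
with a Wald 95% CI on the log scale. Outcomes are dichotomized at a
60-month horizon: an event at or before the horizon is "poor", censoring
at or after it is "good", censoring before it is "excluded"; events after
the horizon count as "good" (no event within five years, adequate
follow-up). Discrimination is the ROC AUC of the continuous score against
the dichotomized outcome, with a DeLong confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

HORIZON_MONTHS = 60.0


@dataclass
class KmCurve:
    """Product-limit estimate: S(t) just after each distinct event time."""

    event_times: np.ndarray  # increasing, distinct times with >= 1 event
    survival: np.ndarray  # S(t) at those times; non-increasing, starts <= 1
    at_risk: np.ndarray  # risk-set size just before each event time

    def survival_at(self, t: float) -> float:
        """Step-function lookup; S = 1 before the first event time."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class HrEstimate:
    hr: float
    ci_low: float
    ci_high: float
    p_value: float
    log_hr_se: float
    converged: bool = True


def _check_surv(times, events):
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("empty survival input")
    if times.shape != events.shape:
        raise ValueError("times and events must have equal length")
    if (times < 0).any():
        raise ValueError("negative survival time")
    if not np.isin(events, (0, 1)).all():
        raise ValueError("events must be 0 or 1")
    return times, events


def km_estimate(times, events) -> KmCurve:
    """Kaplan-Meier product-limit estimator (right censoring)."""
    times, events = _check_surv(times, events)
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    table = kmf.event_table
    mask = table["observed"] > 0
    event_times = table.index[mask].to_numpy(dtype=float)
    at_risk = table.loc[mask, "at_risk"].to_numpy(dtype=int)
    sf = kmf.survival_function_["KM_estimate"]
    survival = sf.loc[event_times].to_numpy(dtype=float)
    return KmCurve(event_times=event_times, survival=survival, at_risk=at_risk)


def logrank(times, events, group) -> tuple[float, float]:
    """Log-rank test across 2+ groups (k-1 degrees of freedom)."""
    times, events = _check_surv(times, events)
    group = np.asarray(group)
    labels, counts = np.unique(group, return_counts=True)
    if labels.size < 2:
        raise ValueError("log-rank needs at least two non-empty groups")
    res = multivariate_logrank_test(times, group, events)
    return float(res.test_statistic), float(res.p_value)


def cox_binary_hr(times, events, indicator, max_iter: int = 50) -> HrEstimate:
    """Cox HR for one binary covariate, Breslow ties, Wald 95% CI.

    Newton iteration on the partial log-likelihood

        l(b) = b * S1 - sum_j d_j * log(n0_j + n1_j * exp(b))

    over distinct event times t_j, where d_j is the event count, S1 the
    total events in the indicator-1 group, and n0_j/n1_j the risk-set sizes
    per group. A monotone likelihood (all events on one side with no
    risk-set overlap) cannot converge and is flagged instead of raising.
    """
    times, events = _check_surv(times, events)
    x = np.asarray(indicator, dtype=int)
    if np.unique(x).size < 2:
        raise ValueError("indicator is constant; both levels required")
    if events.sum() == 0:
        raise ValueError("no events observed")

    event_times = np.unique(times[events == 1])
    d = np.zeros(event_times.size)
    s1 = np.zeros(event_times.size)
    n1 = np.zeros(event_times.size)
    n0 = np.zeros(event_times.size)
    for j, t in enumerate(event_times):
        at_event = (times == t) & (events == 1)
        d[j] = at_event.sum()
        s1[j] = (at_event & (x == 1)).sum()
        at_risk = times >= t
        n1[j] = (at_risk & (x == 1)).sum()
        n0[j] = (at_risk & (x == 0)).sum()
    S1 = s1.sum()

    b = 0.0
    converged = False
    for _ in range(max_iter):
        eb = np.exp(b)
        denom = n0 + n1 * eb
        grad = S1 - np.sum(d * n1 * eb / denom)
        info = np.sum(d * n1 * n0 * eb / denom**2)
        if info <= 0 or abs(b) > 30:
            break
        step = grad / info
        b += np.clip(step, -2.0, 2.0)
        if abs(step) < 1e-10:
            converged = True
            break
    eb = np.exp(b)
    info = np.sum(d * n1 * n0 * eb / (n0 + n1 * eb) ** 2)
    se = np.sqrt(1.0 / info) if info > 0 else np.inf
    z = stats.norm.ppf(0.975)
    if not np.isfinite(se):
        return HrEstimate(
            hr=float(np.exp(b)), ci_low=0.0, ci_high=np.inf,
            p_value=np.nan, log_hr_se=np.inf, converged=False,
        )
    p = 2 * stats.norm.sf(abs(b / se))

    def _safe_exp(v: float) -> float:
        return float(np.exp(v)) if v < 700 else np.inf

    return HrEstimate(
        hr=float(np.exp(b)),
        ci_low=_safe_exp(b - z * se),
        ci_high=_safe_exp(b + z * se),
        p_value=float(p),
        log_hr_se=float(se),
        converged=converged,
    )


def dichotomize(times, events, horizon_months: float = HORIZON_MONTHS) -> np.ndarray:
    """Label each sample poor / good / excluded at a follow-up horizon."""
    times, events = _check_surv(times, events)
    labels = np.full(times.shape, "excluded", dtype=object)
    labels[times >= horizon_months] = "good"
    # poor last: an event at exactly the horizon is "within 5 years"
    labels[(events == 1) & (times <= horizon_months)] = "poor"
    return labels


def _delong_placements(poor: np.ndarray, good: np.ndarray):
    m, n = poor.size, good.size
    all_scores = np.concatenate([poor, good])
    tx = stats.rankdata(all_scores)  # midranks
    tp = stats.rankdata(poor)
    tg = stats.rankdata(good)
    v10 = (tx[:m] - tp) / n  # per-poor placement
    v01 = 1.0 - (tx[m:] - tg) / m  # per-good placement
    return v10, v01


def roc_auc(scores, labels) -> tuple[float, float, float]:
    """AUC of a score for the poor outcome, with a DeLong 95% CI.

    AUC is the probability that a random poor-labelled sample outscores a
    random good-labelled one, ties counting one half. ``labels`` contains
    "poor"/"good" only; drop "excluded" samples beforehand.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if not set(np.unique(labels)) <= {"poor", "good"}:
        raise ValueError("labels must be 'poor'/'good' (excluded removed)")
    poor = scores[labels == "poor"]
    good = scores[labels == "good"]
    if poor.size == 0 or good.size == 0:
        raise ValueError("both outcome classes must be present")
    v10, v01 = _delong_placements(poor, good)
    auc = float(v10.mean())
    var = 0.0
    if poor.size > 1:
        var += np.var(v10, ddof=1) / poor.size
    if good.size > 1:
        var += np.var(v01, ddof=1) / good.size
    se = np.sqrt(var)
    z = stats.norm.ppf(0.975)
    return auc, float(max(0.0, auc - z * se)), float(min(1.0, auc + z * se))
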