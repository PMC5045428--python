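"""Survival evaluation: Kaplan-Meier, log-rank, time-dependent ROC, C-index.

Kaplan-Meier estimation and log-rank tests are delegated to
:mod:`lifelines`.  The time-dependent ROC is the cumulative-case /
dynamic-control estimator at a fixed horizon with inverse-probability-of-
censoring weights from the Kaplan-Meier estimate of the censoring
distribution.  Harrell's C is computed by explicit pairwise comparison
(ties in score count 0.5; pairs whose order is indeterminate under
censoring are excluded from the denominator).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

__all__ = [
    "KMCurve",
    "LogRankResult",
    "TimeROC",
    "ConcordanceResult",
    "kaplan_meier",
    "survival_at",
    "log_rank",
    "time_dependent_roc",
    "harrell_c",
    "stratified_logrank_by",
]


@dataclass(frozen=True)
class KMCurve:
    """Product-limit survival estimate as a right-continuous step function."""

    times: np.ndarray  # step locations, ascending, starting at 0
    survival: np.ndarray  # S(t) for t in [times[i], times[i+1])
    at_risk: np.ndarray

    def __call__(self, t: float) -> float:
        return survival_at(self, t)


@dataclass(frozen=True)
class LogRankResult:
    statistic: float
    df: int
    p: float


@dataclass(frozen=True)
class TimeROC:
    horizon: float
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float


@dataclass(frozen=True)
class ConcordanceResult:
    c_index: float
    n_pairs: int


def _check_surv(time, event) -> tuple[np.ndarray, np.ndarray]:
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(int)
    if (time < 0).any():
        raise ValueError("survival times must be non-negative")
    if time.shape != event.shape:
        raise ValueError("time and event must align")
    return time, event


def kaplan_meier(time, event) -> KMCurve:
    """Kaplan-Meier product-limit estimate of the survival function."""
    time, event = _check_surv(time, event)
    kmf = KaplanMeierFitter()
    kmf.fit(time, event)
    sf = kmf.survival_function_
    times = sf.index.to_numpy(dtype=float)
    survival = sf.iloc[:, 0].to_numpy(dtype=float)
    at_risk = kmf.event_table["at_risk"].reindex(sf.index).to_numpy(dtype=float)
    return KMCurve(times=times, survival=survival, at_risk=at_risk)


def survival_at(curve: KMCurve, t: float) -> float:
    """Evaluate S(t) with the right-continuous step convention; S(t<0)=1."""
    idx = np.searchsorted(curve.times, t, side="right") - 1
    if idx < 0:
        return 1.0
    return float(curve.survival[idx])


def log_rank(groups, time, event) -> LogRankResult:
    """Two-sided log-rank test across >=2 groups (df = n_groups - 1)."""
    time, event = _check_surv(time, event)
    groups = np.asarray(groups)
    levels = pd.unique(groups)
    if len(levels) < 2:
        raise ValueError("log-rank test needs at least two groups")
    res = multivariate_logrank_test(time, groups, event)
    return LogRankResult(
        statistic=float(res.test_statistic), df=len(levels) - 1, p=float(res.p_value)
    )


def _censoring_km(time: np.ndarray, event: np.ndarray) -> KMCurve:
    return kaplan_meier(time, 1 - event)


def time_dependent_roc(scores, time, event, horizon: float = 5.0) -> TimeROC:
    """Cumulative/dynamic ROC for event-by-horizon prediction under censoring.

    Cases are patients with an observed event at or before the horizon,
    controls those still event-free beyond it; patients censored before the
    horizon are removed via inverse-probability-of-censoring weights (cases
    by 1/G(T-), controls by 1/G(horizon), with G the Kaplan-Meier estimate
    of the censoring survival function).  The AUC is the trapezoidal area
    under the weighted sensitivity/1-specificity staircase, which reduces to
    the plain rank-sum AUC when no one is censored before the horizon.
    """
    time, event = _check_surv(time, event)
    scores = np.asarray(scores, dtype=float)
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    case = (time <= horizon) & (event == 1)
    control = time > horizon
    if not case.any() or not control.any():
        raise ValueError("need at least one case and one control at the horizon")

    G = _censoring_km(time, event)
    eps = 1e-10
    w = np.zeros_like(scores)
    g_case = np.array([survival_at(G, t - eps) for t in time[case]])
    w[case] = 1.0 / np.maximum(g_case, eps)
    w[control] = 1.0 / max(survival_at(G, horizon), eps)

    thresholds = np.unique(scores)[::-1]
    w_case_total = w[case].sum()
    w_ctrl_total = w[control].sum()
    sens = np.array(
        [w[case & (scores >= c)].sum() / w_case_total for c in thresholds]
    )
    fpr = np.array(
        [w[control & (scores >= c)].sum() / w_ctrl_total for c in thresholds]
    )
    auc = float(np.trapezoid(np.r_[0.0, sens, 1.0], np.r_[0.0, fpr, 1.0]))
    return TimeROC(
        horizon=horizon,
        thresholds=thresholds,
        sensitivity=sens,
        specificity=1.0 - fpr,
        auc=auc,
    )


def harrell_c(scores, time, event) -> ConcordanceResult:
    """Harrell's concordance index of a risk score against survival.

    A pair is usable when the ordering of event times is determined: the
    earlier patient had an observed event (including an event tied with the
    other patient's censoring time).  Higher score is expected for the
    earlier event; score ties count 0.5.  C=1 is perfect discrimination,
    C=0.5 chance.
    """
    time, event = _check_surv(time, event)
    scores = np.asarray(scores, dtype=float)
    t_i = time[:, None]
    t_j = time[None, :]
    e_i = (event == 1)[:, None]
    e_j = (event == 1)[None, :]
    # i strictly earlier with event, or tied time: event before censoring
    usable = ((t_i < t_j) & e_i) | ((t_i == t_j) & e_i & ~e_j)
    s_i = scores[:, None]
    s_j = scores[None, :]
    concordant = (usable & (s_i > s_j)).sum()
    tied = (usable & (s_i == s_j)).sum()
    n_pairs = int(usable.sum())
    if n_pairs == 0:
        raise ValueError("no usable pairs (all censored or fully tied)")
    return ConcordanceResult(
        c_index=float((concordant + 0.5 * tied) / n_pairs), n_pairs=n_pairs
    )


def stratified_logrank_by(
    time, event, groups, strata, min_stratum_size: int = 10
) -> pd.DataFrame:
    """Log-rank test of ``groups`` run separately within each stratum.

    Strata smaller than ``min_stratum_size`` or containing a single group
    level are reported as skipped (with the reason) rather than tested,
    mirroring the usual exclusion of tiny subgroups from stratified
    analyses.  Returns a long table: stratum, n, statistic, df, p,
    skipped_reason.
    """
    time, event = _check_surv(time, event)
    groups = np.asarray(groups)
    strata = np.asarray(strata)
    rows = []
    for level in pd.unique(strata):
        mask = strata == level
        n = int(mask.sum())
        row = {"stratum": level, "n": n, "statistic": np.nan, "df": np.nan,
               "p": np.nan, "skipped_reason": ""}
        if n < min_stratum_size:
            row["skipped_reason"] = f"below minimum stratum size ({min_stratum_size})"
        elif len(pd.unique(groups[mask])) < 2:
            row["skipped_reason"] = "single group level in stratum"
        else:
            res = log_rank(groups[mask], time[mask], event[mask])
            row.update(statistic=res.statistic, df=res.df, p=res.p)
        rows.append(row)
    return pd.DataFrame(rows)
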