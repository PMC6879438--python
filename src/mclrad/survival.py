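"""Survival analysis and ROC dichotomization for risk-group prognostication.

Thin, contract-checked wrappers around lifelines: Kaplan-Meier
product-limit curves with median survival, the k-sample log-rank test, and
Cox proportional-hazards ratios for categorical risk groups against a
reference level (Wald confidence intervals).  ROC cut-offs maximize
Youden's J over midpoints between adjacent sorted unique values, with the
AUC computed by the rank (Mann-Whitney) statistic counting ties as half.

Conventions: p-values are two-sided; at tied times events are handled by
the product-limit convention (events before censorings) in the KM curve,
and by lifelines' Efron approximation in the Cox partial likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

__all__ = [
    "KMCurve",
    "LogRankResult",
    "CoxResult",
    "CutoffResult",
    "km_estimate",
    "logrank_test",
    "cox_hr",
    "roc_cutoff",
    "auc_mann_whitney",
    "plot_km",
]


@dataclass
class KMCurve:
    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    median: float | None

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.times, "survival": self.survival, "at_risk": self.at_risk}
        )


@dataclass
class LogRankResult:
    statistic: float
    df: int
    p_value: float


@dataclass
class CoxResult:
    """Hazard ratios of each non-reference group versus the reference."""

    reference: str
    groups: list
    hazard_ratios: dict
    ci_lower: dict
    ci_upper: dict
    p_values: dict


@dataclass
class CutoffResult:
    cutoff: float
    sensitivity: float
    specificity: float
    auc: float


def _check_surv(times, events) -> tuple[np.ndarray, np.ndarray]:
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(bool)
    if times.size == 0:
        raise ValueError("empty survival input")
    if times.shape != events.shape:
        raise ValueError("times and events must have equal length")
    if np.any(times < 0) or np.any(~np.isfinite(times)):
        raise ValueError("times must be finite and non-negative")
    return times, events


def km_estimate(times, events) -> KMCurve:
    """Product-limit survival curve, numbers at risk and median survival.

    The median is the smallest observed time with S(t) <= 0.5 and is None
    when the curve never reaches 0.5.
    """
    times, events = _check_surv(times, events)
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    tl = kmf.event_table.index.to_numpy(dtype=float)
    surv = kmf.survival_function_["KM_estimate"].to_numpy()
    at_risk = kmf.event_table["at_risk"].to_numpy()
    med = kmf.median_survival_time_
    median = None if np.isinf(med) else float(med)
    return KMCurve(times=tl, survival=surv, at_risk=at_risk, median=median)


def logrank_test(times, events, groups) -> LogRankResult:
    """K-sample log-rank test (observed vs expected events, chi-square)."""
    times, events = _check_surv(times, events)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if labels.size < 2:
        raise ValueError("log-rank test needs at least 2 groups")
    res = multivariate_logrank_test(times, groups, events)
    return LogRankResult(
        statistic=float(res.test_statistic),
        df=int(labels.size - 1),
        p_value=float(res.p_value),
    )


def cox_hr(times, events, groups, reference=None) -> CoxResult:
    """Cox proportional-hazards ratios for group indicators vs a reference.

    Fits a partial-likelihood model with one indicator per non-reference
    group; a fit without a single event, or that fails to converge, raises
    rather than returning a silent estimate.
    """
    times, events = _check_surv(times, events)
    groups = np.asarray(groups)
    labels = list(pd.unique(groups))
    if len(labels) < 2:
        raise ValueError("Cox contrast needs at least 2 groups")
    if reference is None:
        reference = sorted(map(str, labels))[0]
        reference = next(l for l in labels if str(l) == reference)
    if reference not in labels:
        raise ValueError(f"reference group {reference!r} not among {labels}")
    if events.sum() == 0:
        raise ValueError("no events observed; hazard ratios are undefined")
    others = [l for l in labels if l != reference]
    df = pd.DataFrame({"time": times, "event": events.astype(int)})
    for l in others:
        df[f"g_{l}"] = (groups == l).astype(float)
    import warnings

    from lifelines.exceptions import ConvergenceWarning

    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", ConvergenceWarning)
            cph.fit(df, duration_col="time", event_col="event")
    except Exception as exc:  # convergence/singularity from lifelines
        raise ValueError(f"Cox fit failed or did not converge: {exc}") from exc
    params = cph.params_.to_numpy()
    ses = cph.standard_errors_.to_numpy()
    if not (np.all(np.isfinite(params)) and np.all(np.isfinite(ses))):
        raise ValueError("Cox fit did not converge to finite estimates")
    if np.any(np.abs(params) > 20):
        raise ValueError("Cox coefficients diverged (monotone likelihood?)")
    summary = cph.summary
    hrs, lo, hi, ps = {}, {}, {}, {}
    for l in others:
        row = summary.loc[f"g_{l}"]
        hrs[l] = float(np.exp(row["coef"]))
        lo[l] = float(np.exp(row["coef lower 95%"]))
        hi[l] = float(np.exp(row["coef upper 95%"]))
        ps[l] = float(row["p"])
    return CoxResult(
        reference=reference, groups=labels, hazard_ratios=hrs,
        ci_lower=lo, ci_upper=hi, p_values=ps,
    )


def auc_mann_whitney(values, labels) -> float:
    """Rank-based AUC: concordant pairs plus half the tied pairs."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n1, n0 = labels.sum(), (~labels).sum()
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(values)
    u = ranks[labels].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def roc_cutoff(values, labels) -> CutoffResult:
    """Optimal dichotomization threshold by Youden's J.

    Candidate cut-offs are the midpoints between adjacent sorted unique
    values ("value > cutoff" is called positive); among cut-offs with equal
    J the one with the higher sensitivity (lower threshold) wins.  The AUC
    is the Mann-Whitney rank statistic.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present")
    auc = auc_mann_whitney(values, labels)
    uniq = np.unique(values)
    if uniq.size < 2:
        raise ValueError("cannot place a cut-off: all values identical")
    candidates = (uniq[:-1] + uniq[1:]) / 2.0
    n1, n0 = labels.sum(), (~labels).sum()
    best = None
    for c in candidates:
        pos = values > c
        sens = (pos & labels).sum() / n1
        spec = (~pos & ~labels).sum() / n0
        j = sens + spec - 1.0
        # strict improvement, or equal J with higher sensitivity
        if best is None or j > best[0] + 1e-12 or (
            abs(j - best[0]) <= 1e-12 and sens > best[1]
        ):
            best = (j, sens, spec, c)
    _, sens, spec, cut = best
    return CutoffResult(
        cutoff=float(cut), sensitivity=float(sens), specificity=float(spec), auc=auc
    )


def plot_km(times, events, groups=None, path=None, title="Progression-free survival"):
    """Basic Kaplan-Meier plot, optionally per group, written to ``path``."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4.5))
    kmf = KaplanMeierFitter()
    if groups is None:
        kmf.fit(times, events)
        kmf.plot_survival_function(ax=ax)
    else:
        groups = np.asarray(groups)
        for label in pd.unique(groups):
            sel = groups == label
            kmf.fit(np.asarray(times)[sel], np.asarray(events)[sel], label=str(label))
            kmf.plot_survival_function(ax=ax)
    ax.set_xlabel("Months")
    ax.set_ylabel("Survival probability")
    ax.set_title(title)
    ax.set_ylim(0, 1.02)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
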