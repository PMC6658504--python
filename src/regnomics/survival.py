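"""Biomarker survival analytics.

Kaplan-Meier estimation, two-sided log-rank comparison, Kaplan-scan optimal
cutoff search, quantile dichotomization, multivariable Cox proportional
hazards (hazard ratio = antilog of the regression coefficient), the
composite Myc score (elementwise max of N-Myc and c-Myc expression),
Pearson correlation, and the log(-log S) proportionality diagnostic.

Standard estimators are delegated: the log-rank statistic to lifelines and
the Cox partial-likelihood fit to statsmodels PHReg (which provides both
Efron and Breslow tie corrections).  The Kaplan-scan procedure — an
exhaustive search over observed expression cutoffs for the split minimizing
the log-rank p — is implemented here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats
from statsmodels.duration.hazard_regression import PHReg

__all__ = [
    "SurvivalRecord",
    "KmCurve",
    "CoxFit",
    "KaplanScanResult",
    "CorrelationResult",
    "km_estimate",
    "logrank_test",
    "kaplan_scan",
    "dichotomize",
    "cox_ph",
    "composite_myc",
    "pearson",
    "loglog_diagnostic",
    "read_cohort_csv",
]


@dataclass(frozen=True)
class SurvivalRecord:
    """One subject's follow-up: time in months and event indicator
    (death for overall survival; relapse/progression/death for
    event-free survival)."""

    time: float
    event: bool

    def __post_init__(self) -> None:
        if self.time <= 0:
            raise ValueError(f"time must be positive, got {self.time}")


def _to_arrays(records: Sequence[SurvivalRecord]) -> tuple[np.ndarray, np.ndarray]:
    t = np.array([r.time for r in records], dtype=float)
    e = np.array([r.event for r in records], dtype=bool)
    return t, e


@dataclass(frozen=True)
class KmCurve:
    """Product-limit survival curve: S(t) stepped at event times."""

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass(frozen=True)
class CoxFit:
    """Per-covariate proportional-hazards estimates.

    ``hazard_ratio`` is exp(beta); ``ci95`` is exp(beta +- 1.96 SE);
    ``p`` is the two-sided Wald p-value.
    """

    covariates: tuple[str, ...]
    coef: np.ndarray
    hazard_ratio: np.ndarray
    ci95: np.ndarray  # shape (k, 2)
    p: np.ndarray

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "coef": self.coef,
            "HR": self.hazard_ratio,
            "HR_lo95": self.ci95[:, 0],
            "HR_hi95": self.ci95[:, 1],
            "p": self.p,
        }, index=list(self.covariates))


@dataclass(frozen=True)
class KaplanScanResult:
    cutoff: float
    min_p: float
    chi2: float
    n_high: int
    scanned_candidates: int


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int


def km_estimate(records: Sequence[SurvivalRecord]) -> KmCurve:
    """Kaplan-Meier product-limit estimator.

    Censored observations reduce the risk set without introducing a step;
    subjects censored exactly at an event time are counted at risk for that
    event (events processed first).
    """
    if len(records) == 0:
        raise ValueError("km_estimate needs at least one record")
    t, e = _to_arrays(records)
    event_times = np.unique(t[e])
    surv, at_risk, events = [], [], []
    s = 1.0
    for et in event_times:
        n_risk = int(np.sum(t >= et))
        d = int(np.sum((t == et) & e))
        s *= 1.0 - d / n_risk
        surv.append(s)
        at_risk.append(n_risk)
        events.append(d)
    return KmCurve(event_times=event_times, survival=np.array(surv),
                   at_risk=np.array(at_risk), events=np.array(events))


def logrank_test(group_a: Sequence[SurvivalRecord],
                 group_b: Sequence[SurvivalRecord]) -> dict[str, float]:
    """Two-sided log-rank comparison of two survival curves (1 df)."""
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValueError("both groups must be nonempty")
    ta, ea = _to_arrays(group_a)
    tb, eb = _to_arrays(group_b)
    if ea.sum() + eb.sum() == 0:
        raise ValueError("log-rank test requires at least one event")
    res = _ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return {"chi2": float(res.test_statistic), "p": float(res.p_value)}


def dichotomize(values: Sequence[float], rule: str = "median",
                cutoff: float | None = None) -> np.ndarray:
    """Boolean high/low labels; ``high`` means strictly above the cutoff.

    ``rule`` is 'median', 'upper_quartile' or 'value' (explicit ``cutoff``).
    Quantiles use linear interpolation between order statistics.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("values must be nonempty")
    if rule == "median":
        c = float(np.quantile(v, 0.5))
    elif rule == "upper_quartile":
        c = float(np.quantile(v, 0.75))
    elif rule == "value":
        if cutoff is None:
            raise ValueError("rule='value' requires an explicit cutoff")
        c = float(cutoff)
    else:
        raise ValueError(f"unknown dichotomization rule {rule!r}")
    return v > c


def kaplan_scan(values: Sequence[float], records: Sequence[SurvivalRecord],
                lower_q: float = 0.1, upper_q: float = 0.9) -> KaplanScanResult:
    """Optimal expression cutoff by exhaustive log-rank scanning.

    Every observed expression value within the [lower_q, upper_q] quantile
    band is tried as a strict high/low split; the cutoff minimizing the
    two-sided log-rank p is returned (p unadjusted for the scan).  Ties on p
    break toward the smaller high group, then the lower cutoff.
    """
    v = np.asarray(values, dtype=float)
    if len(v) != len(records):
        raise ValueError("values and records must have equal length")
    if np.all(v == v[0]):
        raise ValueError("expression values are constant; no cutoff exists")
    if not any(r.event for r in records):
        raise ValueError("kaplan_scan requires at least one event")
    lo, hi = np.quantile(v, [lower_q, upper_q])
    candidates = np.unique(v[(v >= lo) & (v <= hi)])
    best: tuple[float, int, float, float] | None = None  # (p, n_high, cutoff, chi2)
    scanned = 0
    for c in candidates:
        high = v > c
        if high.sum() == 0 or (~high).sum() == 0:
            continue
        scanned += 1
        res = logrank_test([r for r, h in zip(records, high) if h],
                           [r for r, h in zip(records, high) if not h])
        key = (res["p"], int(high.sum()), float(c), res["chi2"])
        if best is None or (key[0], key[1], key[2]) < (best[0], best[1], best[2]):
            best = key
    if best is None:
        raise ValueError("no valid split in the candidate quantile band")
    p, n_high, cutoff, chi2 = best
    return KaplanScanResult(cutoff=cutoff, min_p=p, chi2=chi2, n_high=n_high,
                            scanned_candidates=scanned)


def cox_ph(design: pd.DataFrame, records: Sequence[SurvivalRecord],
           ties: str = "efron") -> CoxFit:
    """Multivariable Cox proportional-hazards fit.

    Maximizes the partial likelihood with the chosen tie correction
    ('efron' default, 'breslow' alternative).  Hazard ratios are the
    antilogs of the regression coefficients; 95% CIs are
    exp(beta +- 1.96 SE) and p-values are two-sided Wald.
    """
    if ties not in ("efron", "breslow"):
        raise ValueError("ties must be 'efron' or 'breslow'")
    t, e = _to_arrays(records)
    if e.sum() == 0:
        raise ValueError("Cox model requires at least one event")
    X = design.astype(float)
    variances = X.var(axis=0)
    dead = variances[variances == 0].index.tolist()
    if dead:
        raise ValueError(f"zero-variance covariates: {dead}")
    model = PHReg(t, X.to_numpy(), status=e.astype(int), ties=ties)
    res = model.fit(disp=False)
    beta = np.asarray(res.params)
    se = np.asarray(res.bse)
    hr = np.exp(beta)
    ci = np.column_stack([np.exp(beta - 1.959963984540054 * se),
                          np.exp(beta + 1.959963984540054 * se)])
    p = 2.0 * stats.norm.sf(np.abs(beta / se))
    return CoxFit(covariates=tuple(X.columns), coef=beta, hazard_ratio=hr,
                  ci95=ci, p=p)


def composite_myc(nmyc: Sequence[float], cmyc: Sequence[float]) -> np.ndarray:
    """Composite Myc expression: elementwise max of N-Myc and c-Myc values."""
    a = np.asarray(nmyc, dtype=float)
    b = np.asarray(cmyc, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    return np.maximum(a, b)


def pearson(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Sample Pearson correlation with two-sided p from the t-transform on
    n - 2 degrees of freedom."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size != ya.size:
        raise ValueError("x and y must have equal length")
    if xa.size < 3:
        raise ValueError("pearson requires n >= 3")
    if np.all(xa == xa[0]) or np.all(ya == ya[0]):
        raise ValueError("pearson requires nonconstant inputs")
    r, p = stats.pearsonr(xa, ya)
    return CorrelationResult(r=float(r), p=float(p), n=int(xa.size))


def loglog_diagnostic(curves: Mapping[str, KmCurve]
                      ) -> dict[str, np.ndarray]:
    """Per-group (log t, log(-log S(t))) series for the visual
    proportional-hazards check (parallel curves suggest proportionality).

    Steps with S = 1 or S = 0 are dropped (the transform is undefined
    there); a group with no usable steps yields an empty series with a
    warning.
    """
    out: dict[str, np.ndarray] = {}
    for name, curve in curves.items():
        mask = (curve.survival > 0) & (curve.survival < 1) & (curve.event_times > 0)
        if not mask.any():
            warnings.warn(f"group {name!r}: no steps with S in (0,1); empty series")
            out[name] = np.empty((0, 2))
            continue
        t = curve.event_times[mask]
        s = curve.survival[mask]
        out[name] = np.column_stack([np.log(t), np.log(-np.log(s))])
    return out


def read_cohort_csv(source) -> pd.DataFrame:
    """Cohort table: sample_id, expression columns, the three prognostic
    covariates (mycn_amplified, age_gt_18m, stage_unfavorable) and the
    OS/EFS time+event columns."""
    df = pd.read_csv(source)
    required = {"sample_id", "os_time", "os_event"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cohort CSV missing columns: {sorted(missing)}")
    return df


def records_from_frame(df: pd.DataFrame, endpoint: str = "os"
                       ) -> list[SurvivalRecord]:
    """Build SurvivalRecords from a cohort table for endpoint 'os' or 'efs'."""
    tcol, ecol = f"{endpoint}_time", f"{endpoint}_event"
    return [SurvivalRecord(float(t), bool(e))
            for t, e in zip(df[tcol], df[ecol])]
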