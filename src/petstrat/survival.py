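"""Censored-outcome machinery for progression-free survival (PFS).

PFS runs from initial diagnosis to relapse, progression or death, censored
at last follow-up.  This module builds the PFS endpoint from dates, fits
Kaplan-Meier curves with Greenwood confidence bands, computes k-group
log-rank tests from counting-process sums, and fits Cox proportional-hazards
models (Efron tie handling by default, Breslow optional) with Wald
inference.  A univariate screen at alpha = 0.05 selects covariates for the
multivariate models; the three metabolic parameters (SUVmax, TMTV, TLG) are
entered into separate multivariate models because they are near-collinear
measures of the same tumor burden.
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats
from statsmodels.duration.hazard_regression import PHReg

logger = logging.getLogger("petstrat")

DAYS_PER_MONTH = 30.44


def compute_pfs(
    diagnosis_date,
    end_date,
    event_flag: int,
    days_per_month: float = DAYS_PER_MONTH,
) -> tuple[float, int]:
    """PFS interval in months from diagnosis to event or last follow-up.

    `event_flag` is 1 for relapse/progression/death (death counts as a PFS
    event even without documented progression), 0 for censoring at last
    follow-up.  Dates may be ISO strings or date/datetime objects.
    """

    def _to_date(d):
        if isinstance(d, str):
            return _dt.date.fromisoformat(d)
        if isinstance(d, _dt.datetime):
            return d.date()
        return d

    d0, d1 = _to_date(diagnosis_date), _to_date(end_date)
    days = (d1 - d0).days
    if days < 0:
        raise ValueError("end date precedes diagnosis date")
    return days / days_per_month, int(bool(event_flag))


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------


@dataclass
class KMEstimate:
    """Product-limit estimate with Greenwood-based confidence band.

    ``survival_at(t)`` evaluates S(t) = prod_{t_i <= t} (1 - d_i/n_i): the
    step function is right-continuous and the value *at* an event time
    includes that drop.
    """

    fitter: KaplanMeierFitter

    def survival_at(self, t) -> np.ndarray | float:
        s = self.fitter.predict(t)
        return float(s) if np.isscalar(t) else np.asarray(s)

    def ci_at(self, t) -> tuple[float, float]:
        ci = self.fitter.confidence_interval_survival_function_
        idx = ci.index.searchsorted(t, side="right") - 1
        row = ci.iloc[max(idx, 0)]
        return float(row.iloc[0]), float(row.iloc[1])

    @property
    def timeline(self) -> np.ndarray:
        return self.fitter.timeline


def km_estimate(times, events, alpha: float = 0.05) -> KMEstimate:
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("need at least one observation")
    kmf = KaplanMeierFitter(alpha=alpha)
    kmf.fit(times, events)
    return KMEstimate(kmf)


# ---------------------------------------------------------------------------
# Log-rank
# ---------------------------------------------------------------------------


def logrank(groups: list[tuple[np.ndarray, np.ndarray]]) -> tuple[float, int, float]:
    """k-group log-rank test from counting-process sums.

    Returns (chi2, df, p) with df = k - 1.  Raises on an empty group.
    """
    k = len(groups)
    if k < 2:
        raise ValueError("need at least two groups")
    times, events, labels = [], [], []
    for g, (t, e) in enumerate(groups):
        t = np.asarray(t, dtype=float)
        e = np.asarray(e, dtype=int)
        if t.size == 0:
            raise ValueError(f"group {g} is empty")
        times.append(t)
        events.append(e)
        labels.append(np.full(t.size, g))
    t = np.concatenate(times)
    e = np.concatenate(events)
    g = np.concatenate(labels)
    if e.sum() == 0:
        raise ValueError("no events in any group")

    event_times = np.unique(t[e == 1])
    # at-risk and event counts per group at each event time
    n_at = np.array([[(t[g == j] >= tk).sum() for tk in event_times] for j in range(k)])
    d_at = np.array(
        [[((t[g == j] == tk) & (e[g == j] == 1)).sum() for tk in event_times]
         for j in range(k)]
    )
    n_tot = n_at.sum(axis=0).astype(float)
    d_tot = d_at.sum(axis=0).astype(float)

    O = d_at.sum(axis=1).astype(float)
    E = (d_tot * n_at / n_tot).sum(axis=1)
    # covariance of (O - E) over the first k-1 groups
    with np.errstate(divide="ignore", invalid="ignore"):
        mult = np.where(n_tot > 1, d_tot * (n_tot - d_tot) / (n_tot - 1), 0.0)
    V = np.zeros((k - 1, k - 1))
    p_at = n_at / n_tot
    for a in range(k - 1):
        for b in range(k - 1):
            delta = 1.0 if a == b else 0.0
            V[a, b] = np.sum(mult * p_at[a] * (delta - p_at[b]))
    z = (O - E)[: k - 1]
    chi2 = float(z @ np.linalg.pinv(V) @ z)
    df = k - 1
    p = float(stats.chi2.sf(chi2, df))
    return chi2, df, p


def logrank_chi2_scan(
    times: np.ndarray,
    events: np.ndarray,
    group_low: np.ndarray,
) -> np.ndarray:
    """Two-group log-rank chi-squares for many candidate splits at once.

    `group_low` is a (C, n) boolean matrix; row c marks the low group of
    candidate split c.  Vectorized over candidates for the maximally
    selected cutpoint scan.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    G = np.asarray(group_low, dtype=float)
    event_times = np.unique(times[events == 1])
    Y = (times[:, None] >= event_times[None, :]).astype(float)  # (n, T)
    D = ((times[:, None] == event_times[None, :]) & (events[:, None] == 1)).astype(float)
    n_t = Y.sum(axis=0)
    d_t = D.sum(axis=0)
    n1 = G @ Y  # (C, T)
    d1 = G @ D
    oe = (d1 - d_t * n1 / n_t).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        mult = np.where(n_t > 1, d_t * (n_t - d_t) / (n_t - 1), 0.0)
        var = (mult * n1 * (n_t - n1) / n_t**2).sum(axis=1)
        chi2 = np.where(var > 0, oe**2 / var, 0.0)
    return chi2


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------


@dataclass
class CoxResult:
    """Per-covariate Wald inference plus model-level fit statistics."""

    summary: pd.DataFrame  # coef, hr, ci_low, ci_high, se, p per covariate
    loglik: float
    n: int
    n_events: int
    ties: str

    def hr(self, name: str) -> float:
        return float(self.summary.loc[name, "hr"])

    def p(self, name: str) -> float:
        return float(self.summary.loc[name, "p"])

    def ci(self, name: str) -> tuple[float, float]:
        row = self.summary.loc[name]
        return float(row["ci_low"]), float(row["ci_high"])


def cox_fit(
    covariates,
    times,
    events,
    ties: str = "efron",
    alpha: float = 0.05,
) -> CoxResult:
    """Fit a Cox proportional-hazards model by partial likelihood.

    `covariates` is a DataFrame (or 2D array) of numeric covariates; no
    covariate may be constant.  Wald CIs at level 1 - alpha.  Coefficients
    with |beta| > 10 are flagged as likely complete separation.
    """
    if ties not in ("efron", "breslow"):
        raise ValueError("ties must be 'efron' or 'breslow'")
    X = pd.DataFrame(covariates).apply(pd.to_numeric)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if events.sum() < 1:
        raise ValueError("need at least one event")
    for col in X.columns:
        if X[col].nunique() < 2:
            raise ValueError(f"covariate {col!r} is constant")

    model = PHReg(times, X.values, status=events, ties=ties)
    try:
        res = model.fit(maxiter=200, tol=1e-8, disp=False)
    except Exception as exc:  # pragma: no cover - numerical failure path
        raise RuntimeError(f"Cox fit did not converge: {exc}") from exc
    beta = np.asarray(res.params)
    if not np.all(np.isfinite(beta)):
        raise RuntimeError("Cox fit did not converge: non-finite coefficients")
    if np.any(np.abs(beta) > 10):
        logger.warning("very large Cox coefficient: possible complete separation")
    se = np.asarray(res.bse)
    zcrit = stats.norm.ppf(1 - alpha / 2)
    summary = pd.DataFrame(
        {
            "coef": beta,
            "hr": np.exp(beta),
            "ci_low": np.exp(beta - zcrit * se),
            "ci_high": np.exp(beta + zcrit * se),
            "se": se,
            "p": 2 * stats.norm.sf(np.abs(beta / se)),
        },
        index=[str(c) for c in X.columns],
    )
    return CoxResult(
        summary=summary,
        loglik=float(model.loglike(beta)),
        n=len(times),
        n_events=int(events.sum()),
        ties=ties,
    )


def stepwise_univariate_screen(
    records: pd.DataFrame,
    candidates: list[str],
    time_col: str = "time_months",
    event_col: str = "event",
    alpha: float = 0.05,
) -> tuple[list[str], pd.DataFrame]:
    """Univariate Cox screen: keep candidates with Wald p < alpha.

    Returns the selected names (input order preserved) and the full table of
    per-candidate HRs, CIs and p-values, so that screened-out covariates
    remain reportable.
    """
    if not candidates:
        raise ValueError("candidate list is empty")
    rows = []
    for cand in candidates:
        res = cox_fit(records[[cand]], records[time_col], records[event_col])
        row = res.summary.loc[cand]
        rows.append(
            {
                "covariate": cand,
                "hr": row["hr"],
                "ci_low": row["ci_low"],
                "ci_high": row["ci_high"],
                "p": row["p"],
            }
        )
    table = pd.DataFrame(rows).set_index("covariate")
    selected = [c for c in candidates if table.loc[c, "p"] < alpha]
    return selected, table


METABOLIC_PARAMS = ("suv_max", "tmtv_cm3", "tlg")


def multivariate_models(
    records: pd.DataFrame,
    screened: list[str],
    metabolic: tuple[str, ...] = METABOLIC_PARAMS,
    time_col: str = "time_months",
    event_col: str = "event",
    ties: str = "efron",
) -> dict[str, CoxResult]:
    """One multivariate Cox model per screened metabolic parameter.

    Each model contains the screened clinical covariates plus exactly one of
    the (mutually collinear) metabolic burden measures.
    """
    clinical = [c for c in screened if c not in metabolic]
    out: dict[str, CoxResult] = {}
    for m in metabolic:
        if m not in screened:
            continue
        cols = clinical + [m]
        out[m] = cox_fit(
            records[cols], records[time_col], records[event_col], ties=ties
        )
    return out
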