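"""Model performance under censoring.

Implements the comparison machinery for risk models on a censored endpoint:
Harrell's concordance index with a paired-bootstrap model comparison,
cumulative/dynamic time-dependent AUC with inverse-probability-of-censoring
weights (IPCW), decision-curve analysis (net benefit), and a calibration
table of predicted versus Kaplan-Meier-observed survival per risk bin.

Concordance convention: a pair is usable when the patient with the shorter
observed time had the event (equal times: one event, one censored also
counts, the event side treated as earlier).  Ties in the risk score count
one half.  The O(n^2) pairwise definition is what the vectorized code
computes; tests hold it against an explicit double loop and against
scikit-survival.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .survival import km_estimate

logger = logging.getLogger("petstrat")


def _concordance(risk: np.ndarray, times: np.ndarray, events: np.ndarray) -> float:
    risk = np.asarray(risk, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    earlier = (times[:, None] < times[None, :]) | (
        (times[:, None] == times[None, :])
        & (events[:, None] == 1)
        & (events[None, :] == 0)
    )
    usable = earlier & (events[:, None] == 1)
    if not usable.any():
        raise ValueError("no usable pairs: cannot compute concordance")
    higher = risk[:, None] > risk[None, :]
    tied = risk[:, None] == risk[None, :]
    num = (usable & higher).sum() + 0.5 * (usable & tied).sum()
    return float(num / usable.sum())


@dataclass
class CIndexResult:
    c: float
    se: float
    ci: tuple[float, float]


def c_index(
    risk_scores,
    times,
    events,
    n_boot: int = 200,
    seed: int = 0,
    alpha: float = 0.05,
) -> CIndexResult:
    """Harrell's C with a bootstrap standard error and percentile CI."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    risk = np.asarray(risk_scores, dtype=float)
    if times.size < 2 or events.sum() < 1:
        raise ValueError("need at least two patients and one event")
    c = _concordance(risk, times, events)
    rng = np.random.default_rng(seed)
    n = times.size
    boots = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        try:
            boots.append(_concordance(risk[idx], times[idx], events[idx]))
        except ValueError:
            continue
    boots = np.asarray(boots)
    se = float(boots.std(ddof=1)) if boots.size > 1 else float("nan")
    lo, hi = (
        np.percentile(boots, [100 * alpha / 2, 100 * (1 - alpha / 2)])
        if boots.size
        else (float("nan"), float("nan"))
    )
    return CIndexResult(c=c, se=se, ci=(float(lo), float(hi)))


@dataclass
class CompareCResult:
    delta: float  # C_a - C_b
    ci: tuple[float, float]
    p: float
    c_a: float
    c_b: float


def compare_c(
    model_a_risks,
    model_b_risks,
    times,
    events,
    n_boot: int = 2000,
    seed: int = 0,
    alpha: float = 0.05,
) -> CompareCResult:
    """Paired bootstrap comparison of two risk models on the same patients.

    Resamples patients with replacement, recomputes both C-indices on each
    resample, and reports the percentile CI of the difference and a
    two-sided bootstrap p-value.
    """
    ra = np.asarray(model_a_risks, dtype=float)
    rb = np.asarray(model_b_risks, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if ra.shape != rb.shape or ra.shape != times.shape:
        raise ValueError("both models must score the same patients")
    if n_boot < 100:
        warnings.warn("n_boot < 100 gives unstable bootstrap intervals")
    c_a = _concordance(ra, times, events)
    c_b = _concordance(rb, times, events)
    rng = np.random.default_rng(seed)
    n = times.size
    deltas = []
    while len(deltas) < n_boot:
        idx = rng.integers(0, n, n)
        try:
            deltas.append(
                _concordance(ra[idx], times[idx], events[idx])
                - _concordance(rb[idx], times[idx], events[idx])
            )
        except ValueError:
            continue
    deltas = np.asarray(deltas)
    lo, hi = np.percentile(deltas, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    p = 2.0 * min((deltas <= 0).mean(), (deltas >= 0).mean())
    return CompareCResult(
        delta=c_a - c_b, ci=(float(lo), float(hi)), p=float(min(1.0, p)),
        c_a=c_a, c_b=c_b,
    )


def _censoring_survival(times: np.ndarray, events: np.ndarray):
    """KM of the censoring distribution G(t) (events flipped)."""
    return km_estimate(times, 1 - events)


def td_auc(risk_scores, times, events, horizon_months: float) -> float:
    """Cumulative/dynamic AUC at a horizon with IPCW case weights.

    Cases are patients with an observed event at or before the horizon,
    weighted by 1/G(t-) where G is the Kaplan-Meier estimate of the
    censoring distribution; controls are patients still at risk past the
    horizon.  Tied risk scores count one half.
    """
    risk = np.asarray(risk_scores, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if horizon_months <= 0 or horizon_months >= times.max():
        raise ValueError("horizon must lie within the follow-up range")
    cases = (times <= horizon_months) & (events == 1)
    controls = times > horizon_months
    if not cases.any():
        raise ValueError("no events before the horizon")
    if not controls.any():
        raise ValueError("no controls past the horizon")
    G = _censoring_survival(times, events)
    # left limit of G at each case's event time
    w = 1.0 / np.clip(G.survival_at(times[cases] - 1e-9), 1e-12, None)
    rc = risk[cases][:, None]
    rk = risk[controls][None, :]
    wins = (rc > rk) + 0.5 * (rc == rk)
    num = float((w[:, None] * wins).sum())
    den = float(w.sum() * controls.sum())
    return num / den


def decision_curve(
    event_prob_at_t,
    times,
    events,
    thresholds=None,
    horizon_months: float = 36.0,
) -> pd.DataFrame:
    """Net-benefit curves for the model, treat-all and treat-none.

    At threshold probability pt, patients with predicted event probability
    >= pt are treated.  The true/false-positive fractions among the treated
    are estimated under censoring from the Kaplan-Meier event probability of
    the treated subgroup at the horizon:
    net benefit = TP/n - FP/n * pt/(1-pt).
    """
    pred = np.asarray(event_prob_at_t, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if horizon_months > times.max():
        raise ValueError("horizon beyond the observed follow-up")
    if thresholds is None:
        thresholds = np.arange(0.01, 1.0, 0.01)
    thresholds = np.asarray(thresholds, dtype=float)
    if np.any((thresholds <= 0) | (thresholds >= 1)):
        raise ValueError("thresholds must lie strictly inside (0, 1)")

    n = times.size
    overall_event = 1.0 - km_estimate(times, events).survival_at(horizon_months)
    rows = []
    for pt in thresholds:
        treated = pred >= pt
        if treated.any():
            ev = 1.0 - km_estimate(times[treated], events[treated]).survival_at(
                horizon_months
            )
            frac = treated.sum() / n
            tp, fp = ev * frac, (1.0 - ev) * frac
            nb_model = tp - fp * pt / (1 - pt)
        else:
            nb_model = 0.0
        nb_all = overall_event - (1 - overall_event) * pt / (1 - pt)
        rows.append(
            {
                "threshold": pt,
                "net_benefit_model": nb_model,
                "net_benefit_all": nb_all,
                "net_benefit_none": 0.0,
            }
        )
    return pd.DataFrame(rows)


def calibration(
    pred_surv_at_t,
    times,
    events,
    n_bins: int = 10,
    horizon_months: float = 36.0,
    bin_labels=None,
) -> pd.DataFrame:
    """Calibration table: mean predicted vs KM-observed survival per bin.

    Bins are predicted-survival quantile groups by default; pass
    ``bin_labels`` (e.g. the risk categories) to bin by an explicit grouping
    instead.  Empty bins are dropped with a warning.
    """
    pred = np.asarray(pred_surv_at_t, dtype=float)
    if np.any((pred < 0) | (pred > 1)):
        raise ValueError("predicted survival probabilities must lie in [0, 1]")
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if bin_labels is not None:
        groups = pd.Series(bin_labels)
    else:
        if n_bins > times.size:
            warnings.warn("more bins than patients; reducing bin count")
            n_bins = max(1, times.size)
        groups = pd.qcut(pred, q=n_bins, duplicates="drop")
    rows = []
    for label, idx in pd.Series(range(times.size)).groupby(groups, observed=True):
        sel = idx.values
        if sel.size == 0:
            warnings.warn(f"empty calibration bin {label}; dropped")
            continue
        km = km_estimate(times[sel], events[sel])
        obs = km.survival_at(horizon_months)
        lo, hi = km.ci_at(horizon_months)
        rows.append(
            {
                "bin": str(label),
                "n": int(sel.size),
                "predicted": float(pred[sel].mean()),
                "observed": float(obs),
                "ci_low": lo,
                "ci_high": hi,
            }
        )
    return pd.DataFrame(rows)


def category_event_probabilities(
    categories,
    times,
    events,
    horizon_months: float,
) -> dict[str, float]:
    """KM event probability at the horizon within each risk category (the
    predicted probabilities used for DCA/calibration of ordinal scores)."""
    categories = pd.Series(categories)
    out: dict[str, float] = {}
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    for cat in categories.unique():
        sel = (categories == cat).values
        out[str(cat)] = 1.0 - km_estimate(times[sel], events[sel]).survival_at(
            horizon_months
        )
    return out
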