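"""Optimal cutpoint selection for continuous features against censored
outcomes (maximally selected log-rank statistics).

The scan considers every midpoint between consecutive sorted unique feature
values whose induced split leaves both groups at least ``floor(min_frac*n)``
patients, computes the two-group log-rank chi-square for each admissible
candidate, and returns the maximizer.  Because the maximum over many looks
inflates the naive p-value, the corrected p uses the Miller-Siegmund
approximation for the supremum of the standardized log-rank process over
the admissible quantile band.

The cutoffs published for the 126-patient cohort this package models
(SUVmax 17.60, TMTV 408.72 cm3, TLG 1446.98, Dmax 56.73 cm) cannot be
re-derived without the per-patient data; they ship as the
``PUBLISHED_CUTOFFS`` preset instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .survival import logrank_chi2_scan

#: published optimal cutoffs, used as configuration presets
PUBLISHED_CUTOFFS = {
    "suv_max": 17.60,
    "tmtv_cm3": 408.72,
    "tlg": 1446.98,
    "d_max_cm": 56.73,
}


@dataclass
class CutpointResult:
    cutoff: float
    chi2: float
    p_uncorrected: float
    p_corrected: float
    group_sizes: tuple[int, int]  # (n_low, n_high)


def miller_siegmund_p(b: float, eps_low: float, eps_high: float) -> float:
    """Approximate P(sup |standardized log-rank| > b) over the quantile band
    [eps_low, eps_high] of candidate cutoffs (improved Bonferroni bound for
    a maximally selected rank statistic)."""
    if b <= 1e-12:
        return 1.0
    phi = stats.norm.pdf(b)
    band = np.log((eps_high * (1 - eps_low)) / (eps_low * (1 - eps_high)))
    p = phi * (b - 1.0 / b) * band + 4.0 * phi / b
    return float(min(1.0, max(0.0, p)))


def optimal_cutoff(
    values,
    times_months,
    events,
    min_frac: float = 0.1,
) -> CutpointResult:
    """Maximally selected log-rank cutoff for one continuous feature.

    Raises when no candidate satisfies the group-size constraint or all
    values are identical.  Deterministic: ties in chi-square are broken
    toward the smaller cutoff.
    """
    values = np.asarray(values, dtype=float)
    times = np.asarray(times_months, dtype=float)
    events = np.asarray(events, dtype=int)
    n = values.size
    if n < 10:
        raise ValueError("need at least 10 observations")
    if events.sum() < 1:
        raise ValueError("need at least one event")
    if not 0.0 < min_frac < 0.5:
        raise ValueError("min_frac must lie in (0, 0.5)")

    uniq = np.unique(values)
    if uniq.size < 2:
        raise ValueError("all feature values identical: no candidate cutoff")
    candidates = (uniq[:-1] + uniq[1:]) / 2.0

    n_low = (values[None, :] <= candidates[:, None]).sum(axis=1)
    floor_n = int(np.floor(min_frac * n))
    min_group = max(1, floor_n)
    admissible = (n_low >= min_group) & (n - n_low >= min_group)
    if not admissible.any():
        raise ValueError("no admissible cutoff under the group-size constraint")
    candidates = candidates[admissible]
    n_low = n_low[admissible]

    group_low = values[None, :] <= candidates[:, None]
    chi2 = logrank_chi2_scan(times, events, group_low)
    best = int(np.argmax(chi2))  # argmax takes the first = smallest cutoff on ties
    best_chi2 = float(chi2[best])

    p_unc = float(stats.chi2.sf(best_chi2, 1))
    eps_low = n_low.min() / n
    eps_high = n_low.max() / n
    p_ms = miller_siegmund_p(np.sqrt(best_chi2), eps_low, eps_high)
    p_cor = float(min(1.0, max(p_unc, p_ms)))

    return CutpointResult(
        cutoff=float(candidates[best]),
        chi2=best_chi2,
        p_uncorrected=p_unc,
        p_corrected=p_cor,
        group_sizes=(int(n_low[best]), int(n - n_low[best])),
    )
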