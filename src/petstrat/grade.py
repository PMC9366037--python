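"""Pathologic-grade comparisons (grade 3A vs low-grade follicular lymphoma).

Group comparisons of clinical and PET features between histologic grades:
chi-square / Fisher routing for 2x2 tables, Mann-Whitney U for continuous
features, empirical ROC analysis with a Youden-optimal cutoff and the
derived predictive values, and multivariable logistic regression.

Chi-square tests run without continuity correction; the test routes to
Fisher's exact test when any expected count falls below 5 (the routing can
be overridden with ``method=``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.metrics import roc_curve


def contingency_test(
    table, method: str = "auto"
) -> tuple[float, float, str]:
    """Test association in a 2x2 table.

    Pearson chi-square (no continuity correction) when all expected counts
    are >= 5, otherwise Fisher's exact test; ``method`` may force either
    route.  Returns (statistic, p, method_used); the Fisher statistic is
    the sample odds ratio.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("need a 2x2 table of non-negative counts")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("zero margin: test undefined")
    expected = stats.contingency.expected_freq(t)
    if method == "auto":
        method = "pearson" if expected.min() >= 5 else "fisher"
    if method == "pearson":
        chi2, p, _, _ = stats.chi2_contingency(t, correction=False)
        return float(chi2), float(p), "pearson"
    if method == "fisher":
        odds, p = stats.fisher_exact(t.astype(int))
        return float(odds), float(p), "fisher"
    raise ValueError(f"unknown method {method!r}")


def mann_whitney(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U.

    Exhaustive permutation when both samples have <= 8 observations (tie
    safe), otherwise the normal approximation with tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    if x.size <= 8 and y.size <= 8:
        method = stats.PermutationMethod(n_resamples=np.inf, rng=0)
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


@dataclass
class RocResult:
    auc: float
    cutoff: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    p_auc: float


def roc_binary(values, labels) -> RocResult:
    """Empirical ROC of a continuous marker against a binary label.

    AUC by the trapezoid rule (equals the normalized Mann-Whitney
    statistic); the reported cutoff maximizes Youden's J (sens + spec - 1),
    ties broken toward higher specificity; positives are values >= cutoff.
    The AUC p-value against 0.5 uses the rank-sum normal approximation.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    fpr, tpr, thresholds = roc_curve(labels, values, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    j = tpr - fpr
    # ties toward higher specificity = lower fpr; roc_curve lists thresholds
    # descending, so among tied J pick the smallest fpr
    best = min(np.flatnonzero(j == j.max()), key=lambda i: (fpr[i], -thresholds[i]))
    cutoff = float(thresholds[best])
    if np.isinf(cutoff):  # sklearn's sentinel above the max value
        cutoff = float(values.max())
    pred = values >= cutoff
    tp = int((pred & (labels == 1)).sum())
    fp = int((pred & (labels == 0)).sum())
    fn = n_pos - tp
    tn = n_neg - fp
    sens = tp / n_pos
    spec = tn / n_neg
    ppv = tp / (tp + fp) if tp + fp else float("nan")
    npv = tn / (tn + fn) if tn + fn else float("nan")
    p_auc = float(
        stats.mannwhitneyu(
            values[labels == 1], values[labels == 0],
            alternative="two-sided", method="asymptotic", use_continuity=False,
        ).pvalue
    )
    return RocResult(auc, cutoff, sens, spec, ppv, npv, p_auc)


def ppv_npv_from_sens_spec(
    sens: float, spec: float, n_pos: int, n_neg: int
) -> tuple[float, float]:
    """Predictive values from sensitivity/specificity and the class split.

    Reconstructs the confusion matrix with rounded counts:
    TP = round(sens * n_pos), FP = round((1 - spec) * n_neg).
    """
    if not (0 <= sens <= 1 and 0 <= spec <= 1):
        raise ValueError("rates must lie in [0, 1]")
    if n_pos <= 0 or n_neg <= 0:
        raise ValueError("class counts must be positive")
    tp = round(sens * n_pos)
    fp = round((1 - spec) * n_neg)
    fn = n_pos - tp
    tn = n_neg - fp
    if tp + fp == 0:
        raise ValueError("no predicted positives: PPV undefined")
    if tn + fn == 0:
        raise ValueError("no predicted negatives: NPV undefined")
    return tp / (tp + fp), tn / (tn + fn)


def logistic_fit(covariates, labels, alpha: float = 0.05) -> pd.DataFrame:
    """Multivariable logistic regression by Newton-Raphson ML.

    Returns per-covariate coef, odds ratio, Wald CI and p.  Complete
    separation is flagged as an error.
    """
    X = pd.DataFrame(covariates).apply(pd.to_numeric)
    y = np.asarray(labels, dtype=int)
    if len(X) <= X.shape[1]:
        raise ValueError("need more observations than covariates")
    Xc = sm.add_constant(X)
    try:
        res = sm.Logit(y, Xc).fit(method="newton", tol=1e-8, maxiter=200, disp=False)
    except Exception as exc:
        raise RuntimeError(f"logistic fit failed (possible separation): {exc}") from exc
    if np.any(np.abs(res.params) > 15):
        raise RuntimeError("complete or quasi-complete separation detected")
    conf = res.conf_int(alpha)
    out = pd.DataFrame(
        {
            "coef": res.params,
            "or": np.exp(res.params),
            "ci_low": np.exp(conf[0]),
            "ci_high": np.exp(conf[1]),
            "p": res.pvalues,
        }
    )
    return out.drop(index="const")
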