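"""Risk stratification: the three-factor TLG/Dmax/LDH score and the
established follicular-lymphoma indices (FLIPI, FLIPI2, PRIMA-PI).

The three-factor score counts adverse factors — TLG above its cutoff, Dmax
above its cutoff, elevated LDH — and maps 0-1 factors to low, 2 to
intermediate and 3 to high risk.  Cutoff comparisons are strict (a value
exactly at the cutoff is not adverse).  All four systems are monotone:
adding an adverse factor never lowers the risk category.

Records may carry either precomputed binary flags (``hb_lt12``) or the
underlying continuous value (``hb_g_dl``); both are accepted.  Elevated
beta-2-microglobulin is likewise accepted as a lab flag (``b2mg_elevated``)
or as a value ``b2mg_mg_l`` against a threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

CATEGORIES = ("low", "intermediate", "high")
UNDETERMINED = "undetermined"


@dataclass
class ScoringSystem:
    """Cutoffs of the three-factor prognostic score."""

    tlg_cutoff: float = 1446.98
    dmax_cutoff_cm: float = 56.73
    b2mg_threshold_mg_l: float = 3.0  # used only when no lab flag is given
    category_map: dict[int, str] = field(
        default_factory=lambda: {0: "low", 1: "low", 2: "intermediate", 3: "high"}
    )

    def __post_init__(self) -> None:
        if self.tlg_cutoff <= 0 or self.dmax_cutoff_cm <= 0:
            raise ValueError("cutoffs must be positive")
        if set(self.category_map) != {0, 1, 2, 3}:
            raise ValueError("category map must cover factor counts 0-3")


def _missing(x) -> bool:
    if x is None:
        return True
    try:
        return math.isnan(float(x))
    except (TypeError, ValueError):
        return False


def score_patient(
    tlg,
    d_max_cm,
    ldh_elevated,
    system: ScoringSystem | None = None,
) -> tuple[int | None, str]:
    """Count adverse factors (TLG > cutoff, Dmax > cutoff, elevated LDH) and
    map the count to a risk category.  Missing input -> (None, undetermined)."""
    system = system or ScoringSystem()
    if any(_missing(v) for v in (tlg, d_max_cm, ldh_elevated)):
        return None, UNDETERMINED
    n = (
        int(float(tlg) > system.tlg_cutoff)
        + int(float(d_max_cm) > system.dmax_cutoff_cm)
        + int(bool(ldh_elevated))
    )
    return n, system.category_map[n]


def _flag(record, flag_name, value_name=None, predicate=None):
    """Binary factor from a record: prefer the precomputed flag, fall back to
    the continuous value; None when both are missing."""
    v = record.get(flag_name)
    if not _missing(v):
        return int(bool(v))
    if value_name is not None:
        raw = record.get(value_name)
        if not _missing(raw):
            return int(predicate(float(raw)))
    return None


def _categorize(factors: list, bands: dict[str, range]) -> str:
    if any(f is None for f in factors):
        return UNDETERMINED
    total = sum(factors)
    for cat, band in bands.items():
        if total in band:
            return cat
    raise AssertionError("category bands must be exhaustive")


def flipi(record) -> str:
    """FLIPI: age >= 60, Ann Arbor III-IV, Hb < 12 g/dl, > 4 nodal sites,
    elevated LDH; 0-1 low, 2 intermediate, >= 3 high."""
    record = dict(record)
    factors = [
        _flag(record, "age_ge60", "age_years", lambda a: a >= 60),
        _flag(record, "ann_arbor_34"),
        _flag(record, "hb_lt12", "hb_g_dl", lambda h: h < 12),
        _flag(record, "nodal_gt4", "n_nodal_sites", lambda k: k > 4),
        _flag(record, "ldh_elevated"),
    ]
    return _categorize(
        factors, {"low": range(0, 2), "intermediate": range(2, 3), "high": range(3, 6)}
    )


def flipi2(record) -> str:
    """FLIPI2: age > 60, elevated beta2-microglobulin, Hb < 12 g/dl,
    longest nodal diameter > 6 cm, marrow involvement; 0 low,
    1-2 intermediate, 3-5 high."""
    record = dict(record)
    age = _flag(record, "age_gt60", "age_years", lambda a: a > 60)
    if age is None:  # fall back to the >=60 flag when only that is recorded
        age = _flag(record, "age_ge60")
    factors = [
        age,
        _flag(record, "b2mg_elevated", "b2mg_mg_l", lambda b: b > 3.0),
        _flag(record, "hb_lt12", "hb_g_dl", lambda h: h < 12),
        _flag(record, "lodlin_gt6", "lodlin_cm", lambda d: d > 6),
        _flag(record, "bm_involved"),
    ]
    return _categorize(
        factors, {"low": range(0, 1), "intermediate": range(1, 3), "high": range(3, 6)}
    )


def prima_pi(record) -> str:
    """PRIMA-PI: elevated beta2-microglobulin -> high; otherwise marrow
    involvement -> intermediate; otherwise low."""
    record = dict(record)
    b2mg = _flag(record, "b2mg_elevated", "b2mg_mg_l", lambda b: b > 3.0)
    bm = _flag(record, "bm_involved")
    if b2mg is None or (b2mg == 0 and bm is None):
        return UNDETERMINED
    if b2mg:
        return "high"
    return "intermediate" if bm else "low"


CATEGORY_ORDINAL = {"low": 0, "intermediate": 1, "high": 2}


def add_scores(
    cohort: pd.DataFrame, system: ScoringSystem | None = None
) -> pd.DataFrame:
    """Annotate a cohort table with n_factors, risk_category and the three
    comparator indices (plus ordinal encodings for model evaluation)."""
    system = system or ScoringSystem()
    out = cohort.copy()
    scored = [
        score_patient(r.get("tlg"), r.get("d_max_cm"), r.get("ldh_elevated"), system)
        for r in out.to_dict("records")
    ]
    out["n_factors"] = [s[0] for s in scored]
    out["risk_category"] = [s[1] for s in scored]
    records = out.to_dict("records")
    out["flipi"] = [flipi(r) for r in records]
    out["flipi2"] = [flipi2(r) for r in records]
    out["prima_pi"] = [prima_pi(r) for r in records]
    for col in ("risk_category", "flipi", "flipi2", "prima_pi"):
        out[col + "_ord"] = out[col].map(CATEGORY_ORDINAL)
    return out
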