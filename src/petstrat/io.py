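"""Formats, configuration and logging.

Volumes travel as NIfTI with a JSON sidecar (voxel spacing in mm, and
optionally injected dose / body weight for SUV conversion); organ masks as
label NIfTI (1=liver, 2=spleen, 3=bone marrow); cohorts as CSV with the
column dictionary of :data:`petstrat.synth.COHORT_COLUMNS`; reports and
configuration as JSON.  Voxel indices are 0-based; spacing comes from the
NIfTI header (a sidecar override is logged); all distances are mm
internally, Dmax is reported in cm.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .petquant import PETVolume, to_suv
from .synth import COHORT_COLUMNS

logger = logging.getLogger("petstrat")


@dataclass
class PipelineConfig:
    """Tunable pipeline parameters; the defaults are the cutoffs published
    for the cohort this package models."""

    suvmax_cutoff: float = 17.60
    tmtv_cutoff_cm3: float = 408.72
    tlg_cutoff: float = 1446.98
    dmax_cutoff_cm: float = 56.73
    detect_suv: float = 2.5
    min_lesion_volume_cm3: float = 0.0
    ties: str = "efron"
    horizons_months: tuple[float, ...] = (36.0, 60.0)
    n_boot: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "suvmax_cutoff",
            "tmtv_cutoff_cm3",
            "tlg_cutoff",
            "dmax_cutoff_cm",
            "detect_suv",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if any(h <= 0 for h in self.horizons_months):
            raise ValueError("horizons must be positive")

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = json.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "horizons_months" in raw:
            raw["horizons_months"] = tuple(raw["horizons_months"])
        return cls(**raw)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=list)


def read_volume(
    path,
    sidecar_path=None,
    labels_path=None,
) -> PETVolume:
    """Load a PET volume from NIfTI, honoring the affine.

    Spacing comes from the header zooms; a sidecar ``spacing_mm`` overrides
    it (logged).  When the sidecar carries ``dose_MBq`` and ``weight_kg``
    and declares ``units: Bq/mL``, the grid is converted to SUV.
    """
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    zooms = img.header.get_zooms()[:3]
    origin = tuple(float(x) for x in img.affine[:3, 3])
    sidecar = {}
    if sidecar_path is not None:
        with open(sidecar_path) as fh:
            sidecar = json.load(fh)
    spacing = tuple(float(z) for z in zooms)
    if "spacing_mm" in sidecar:
        spacing = tuple(float(s) for s in sidecar["spacing_mm"])
        logger.info("sidecar spacing override: %s", spacing)
    if any(s <= 0 for s in spacing):
        raise ValueError("missing or non-positive voxel spacing")
    labels = None
    if labels_path is not None:
        lab_img = nib.load(str(labels_path))
        labels = np.asarray(lab_img.get_fdata()).astype(np.int16)
    if sidecar.get("units") == "Bq/mL":
        if "dose_MBq" not in sidecar or "weight_kg" not in sidecar:
            raise ValueError("activity volume needs dose_MBq and weight_kg")
        return to_suv(
            data, sidecar["dose_MBq"], sidecar["weight_kg"], spacing, origin, labels
        )
    return PETVolume(data, spacing, origin, labels)


def write_volume(vol: PETVolume, path, sidecar_path=None, extra_sidecar=None) -> None:
    """Write a PETVolume as NIfTI (+ optional JSON sidecar)."""
    affine = np.diag(list(vol.spacing_mm) + [1.0])
    affine[:3, 3] = vol.origin_mm
    nib.save(nib.Nifti1Image(vol.values.astype(np.float32), affine), str(path))
    if sidecar_path is not None:
        meta = {"spacing_mm": list(vol.spacing_mm), "units": "SUV"}
        meta.update(extra_sidecar or {})
        with open(sidecar_path, "w") as fh:
            json.dump(meta, fh, indent=2)


def write_labels(labels: np.ndarray, spacing_mm, path) -> None:
    affine = np.diag(list(spacing_mm) + [1.0])
    nib.save(nib.Nifti1Image(labels.astype(np.int16), affine), str(path))


def read_cohort(path, required: list[str] | None = None) -> pd.DataFrame:
    """Read a cohort CSV and validate its schema.

    Missing required columns raise an itemized error; extra columns are
    allowed but logged.
    """
    df = pd.read_csv(path)
    required = list(required) if required is not None else list(COHORT_COLUMNS)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"cohort CSV missing required columns: {missing}")
    extra = [c for c in df.columns if c not in required]
    if extra:
        logger.info("cohort CSV has extra columns: %s", extra)
    return df


def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False)


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="list")
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return dataclasses.asdict(obj)
    if isinstance(obj, (set, tuple)):
        return list(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_report(report, path) -> None:
    """Write a (possibly nested) result object as JSON."""
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, default=_jsonable)


def read_report(path):
    with open(path) as fh:
        return json.load(fh)


def setup_logging(log_path=None, level=logging.INFO) -> logging.Logger:
    """Configure the package logger; optional file sink for CLI runs."""
    lg = logging.getLogger("petstrat")
    lg.setLevel(level)
    if not any(isinstance(h, logging.StreamHandler) for h in lg.handlers):
        h = logging.StreamHandler()
        h.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
        lg.addHandler(h)
    if log_path is not None:
        fh = logging.FileHandler(str(log_path))
        fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s: %(message)s"))
        lg.addHandler(fh)
    return lg
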