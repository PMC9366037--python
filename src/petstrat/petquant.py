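"""Lesion-level PET quantification.

Implements the baseline FDG-PET metrics used for lymphoma risk assessment:
standardized uptake values (SUV), per-lesion metabolic tumor volume (MTV)
delineated with the 41%-of-lesion-SUVmax isocontour, total lesion glycolysis
(TLG = MTV x SUVmean summed over lesions), and the lesion-dissemination
metric Dmax (largest physical distance between any two lesion positions,
0 cm for a single lesion).

Conventions
-----------
* Volumes are ``values[i, j, k]`` arrays in NIfTI axis order (x, y, z) with
  anisotropic voxel spacing in mm; physical coordinates are voxel centers,
  ``origin_mm + index * spacing_mm``, 0-based indices.
* Threshold comparisons are closed (``>=``): a voxel exactly at 41% of the
  lesion SUVmax is included.
* Ties at a component's SUVmax are broken by lexicographic (z, y, x) scan
  order of the voxel index.
* Connectivity is the full 26-neighborhood in 3D.
* Distances are computed in mm internally; Dmax is reported in cm.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial.distance import pdist

logger = logging.getLogger("petstrat")

# organ label codes used in mask volumes
LABEL_LIVER = 1
LABEL_SPLEEN = 2
LABEL_BONE_MARROW = 3

#: 26-connectivity structuring element, fixed package-wide
CONNECTIVITY_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class PETVolume:
    """A 3D SUV grid with physical geometry and optional organ labels.

    Parameters
    ----------
    values : ndarray
        SUV (dimensionless), shape (nx, ny, nz), all values >= 0.
    spacing_mm : tuple of float
        Per-axis voxel size in mm, all > 0.
    origin_mm : tuple of float
        Physical position (mm) of the center of voxel (0, 0, 0).
    labels : ndarray or None
        Integer organ mask of the same shape (1=liver, 2=spleen,
        3=bone marrow, 0=none).
    """

    values: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("PET volume must be 3D")
        if np.any(self.values < 0):
            raise ValueError("SUV values must be non-negative")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing_mm must be three positive values")
        self.origin_mm = tuple(float(o) for o in self.origin_mm)
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape != self.values.shape:
                raise ValueError("labels grid must match the SUV grid shape")

    @property
    def voxel_volume_cm3(self) -> float:
        return float(np.prod(self.spacing_mm)) / 1000.0

    def voxel_center_mm(self, index: tuple[int, int, int]) -> np.ndarray:
        """Physical coordinate (mm) of the center of a voxel."""
        return np.asarray(self.origin_mm) + np.asarray(index) * np.asarray(
            self.spacing_mm
        )


def _scan_order_key(index: np.ndarray) -> tuple:
    # lexicographic (z, y, x) scan order for tie-breaking
    return (index[2], index[1], index[0])


def _peak_voxel(values: np.ndarray, mask: np.ndarray) -> tuple[int, int, int]:
    """Voxel index attaining the max of `values` over `mask`, ties broken
    by lexicographic (z, y, x) scan order."""
    vmax = values[mask].max()
    tied = np.argwhere(mask & (values == vmax))
    best = min(tied, key=_scan_order_key)
    return tuple(int(i) for i in best)


@dataclass
class Candidate:
    """A connected super-threshold component, before 41% delineation."""

    mask: np.ndarray  # boolean grid
    peak_index: tuple[int, int, int]
    suv_max: float

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


@dataclass
class Lesion:
    """One delineated lesion with its metabolic metrics.

    Every voxel in ``mask`` has SUV >= 0.41 x ``suv_max``; ``mtv_cm3`` is the
    voxel count times the voxel volume, ``tlg = mtv_cm3 * suv_mean``.
    """

    mask: np.ndarray
    suv_max: float
    suv_mean: float
    mtv_cm3: float
    tlg: float
    peak_position_mm: np.ndarray
    peak_index: tuple[int, int, int]
    organ_tag: str = "node"  # node | spleen | bone_marrow | other
    focal: bool = True

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    def centroid_mm(self, vol: PETVolume) -> np.ndarray:
        idx = np.argwhere(self.mask)
        return np.asarray(vol.origin_mm) + idx.mean(axis=0) * np.asarray(
            vol.spacing_mm
        )


@dataclass
class PatientPET:
    """Patient-level aggregation of lesion metrics."""

    lesions: list[Lesion] = field(default_factory=list)
    suv_max_patient: float = 0.0
    tmtv_cm3: float = 0.0
    tlg_total: float = 0.0
    d_max_cm: float = 0.0


def to_suv(
    activity_bq_ml: np.ndarray,
    injected_dose_MBq: float,
    body_weight_kg: float,
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0),
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0),
    labels: np.ndarray | None = None,
) -> PETVolume:
    """Convert an activity-concentration grid (Bq/mL) to body-weight SUV.

    SUV = activity / (injected dose / body weight), assuming tissue density
    1 g/mL so Bq/mL and Bq/g coincide.  Decay correction is assumed to have
    been applied upstream.
    """
    if injected_dose_MBq <= 0:
        raise ValueError("injected dose must be positive")
    if body_weight_kg <= 0:
        raise ValueError("body weight must be positive")
    activity = np.asarray(activity_bq_ml, dtype=float)
    # dose in Bq per gram of body mass
    dose_per_g = injected_dose_MBq * 1e6 / (body_weight_kg * 1e3)
    return PETVolume(activity / dose_per_g, spacing_mm, origin_mm, labels)


def detect_lesions(
    vol: PETVolume,
    detect_suv: float = 2.5,
    min_volume_cm3: float = 0.0,
    exclusions: np.ndarray | None = None,
) -> list[Candidate]:
    """Find candidate lesions as 26-connected components of SUV >= detect_suv.

    Voxels in `exclusions` (e.g. brain/bladder boxes) are removed before
    labeling; components smaller than `min_volume_cm3` are dropped.
    Components are ordered by SUVmax descending, ties by scan order of the
    peak voxel.  An empty volume yields an empty list.
    """
    if detect_suv <= 0:
        raise ValueError("detect_suv must be positive")
    above = vol.values >= detect_suv
    if exclusions is not None:
        above &= ~np.asarray(exclusions, dtype=bool)
    labeled, n = ndimage.label(above, structure=CONNECTIVITY_26)
    out: list[Candidate] = []
    for comp in range(1, n + 1):
        mask = labeled == comp
        if mask.sum() * vol.voxel_volume_cm3 < min_volume_cm3:
            continue
        peak = _peak_voxel(vol.values, mask)
        out.append(Candidate(mask=mask, peak_index=peak, suv_max=float(vol.values[peak])))
    out.sort(key=lambda c: (-c.suv_max, _scan_order_key(np.asarray(c.peak_index))))
    return out


def delineate_41(
    vol: PETVolume,
    candidate: Candidate,
    threshold_fraction: float = 0.41,
) -> Lesion:
    """Delineate a lesion at ``threshold_fraction`` of its own SUVmax.

    The mask is the subset of the candidate's voxels with
    SUV >= fraction x (candidate SUVmax), restricted to the 26-connected
    piece containing the peak voxel.  The threshold is per lesion (each
    component's own SUVmax), not the patient SUVmax.
    """
    if candidate.n_voxels == 0:
        raise ValueError("candidate component is empty")
    thr = threshold_fraction * candidate.suv_max
    above = candidate.mask & (vol.values >= thr)
    labeled, _ = ndimage.label(above, structure=CONNECTIVITY_26)
    mask = labeled == labeled[candidate.peak_index]
    n_vox = int(mask.sum())
    suv_mean = float(vol.values[mask].mean())
    mtv = n_vox * vol.voxel_volume_cm3
    peak = candidate.peak_index
    return Lesion(
        mask=mask,
        suv_max=candidate.suv_max,
        suv_mean=suv_mean,
        mtv_cm3=mtv,
        tlg=mtv * suv_mean,
        peak_position_mm=vol.voxel_center_mm(peak),
        peak_index=peak,
    )


@dataclass
class Involvement:
    """Outcome of an organ-involvement rule; `involved` is None when the
    required masks were missing and the call could not decide."""

    involved: bool | None
    reason: str


def spleen_involved(
    vol: PETVolume,
    spleen_mask: np.ndarray | None,
    liver_mask: np.ndarray | None,
    candidates: list[Candidate] | None = None,
    detect_suv: float = 2.5,
    min_volume_cm3: float = 0.0,
    diffuse_fraction: float = 0.5,
) -> Involvement:
    """Spleen involvement: focal uptake inside the spleen, or diffuse spleen
    uptake above 150% of the mean liver background.

    A detected component counts as focal only while it covers at most
    ``diffuse_fraction`` of the spleen; a component blanketing the organ is
    diffuse uptake and is judged by the 150%-of-liver rule instead.
    """
    if spleen_mask is None or liver_mask is None:
        logger.warning("spleen involvement undetermined: missing organ mask")
        return Involvement(None, "missing spleen or liver mask")
    spleen_mask = np.asarray(spleen_mask, dtype=bool)
    liver_mask = np.asarray(liver_mask, dtype=bool)
    if not spleen_mask.any() or not liver_mask.any():
        raise ValueError("spleen and liver masks must be nonempty")
    if candidates is None:
        candidates = detect_lesions(vol, detect_suv, min_volume_cm3)
    spleen_total = int(spleen_mask.sum())
    for cand in candidates:
        if spleen_mask[cand.peak_index]:
            overlap = int((cand.mask & spleen_mask).sum())
            if overlap <= diffuse_fraction * spleen_total:
                return Involvement(True, "focal uptake inside spleen")
    spleen_mean = float(vol.values[spleen_mask].mean())
    liver_mean = float(vol.values[liver_mask].mean())
    if spleen_mean > 1.5 * liver_mean:
        return Involvement(
            True,
            f"diffuse uptake {spleen_mean:.2f} > 150% of liver {liver_mean:.2f}",
        )
    return Involvement(False, "no focal or diffuse spleen uptake")


def bone_marrow_filter(
    lesions: list[Lesion],
    bm_mask: np.ndarray | None,
    diffuse_fraction: float = 0.5,
) -> list[Lesion]:
    """Drop diffuse bone-marrow signal from the volume measurement.

    A lesion whose peak voxel lies inside the marrow mask is tagged
    ``bone_marrow``; it is kept only when focal.  A marrow component is
    called diffuse when it covers more than ``diffuse_fraction`` of the
    marrow compartment (there is no canonical quantitative definition of
    "focal"; the fraction is configurable).  Without a mask all lesions
    pass through unchanged.
    """
    if bm_mask is None:
        logger.warning("no bone-marrow mask provided; lesions pass through")
        return list(lesions)
    bm_mask = np.asarray(bm_mask, dtype=bool)
    bm_total = int(bm_mask.sum())
    kept: list[Lesion] = []
    for les in lesions:
        if bm_mask[les.peak_index]:
            les.organ_tag = "bone_marrow"
            overlap = int((les.mask & bm_mask).sum())
            les.focal = bm_total == 0 or overlap <= diffuse_fraction * bm_total
            if not les.focal:
                logger.info("dropping diffuse marrow component (%d voxels)", overlap)
                continue
        kept.append(les)
    return kept


def compute_dmax(
    lesions: list[Lesion],
    vol: PETVolume | None = None,
    mode: str = "peak",
) -> float:
    """Largest pairwise distance between lesion positions, in cm.

    Positions are the lesions' SUVmax voxels by default (``mode='peak'``);
    ``mode='centroid'`` uses mask centroids and requires `vol` for the
    geometry.  0 or 1 lesion gives 0 cm.
    """
    if len(lesions) <= 1:
        return 0.0
    if mode == "peak":
        pts = np.array([les.peak_position_mm for les in lesions], dtype=float)
    elif mode == "centroid":
        if vol is None:
            raise ValueError("centroid mode requires the PETVolume")
        pts = np.array([les.centroid_mm(vol) for les in lesions])
    else:
        raise ValueError(f"unknown Dmax mode {mode!r}")
    return float(pdist(pts).max()) / 10.0


def summarize_patient(lesions: list[Lesion]) -> PatientPET:
    """Aggregate lesions: patient SUVmax, TMTV, total TLG and Dmax."""
    if not lesions:
        logger.warning("no lesions: patient metrics all zero")
        return PatientPET()
    return PatientPET(
        lesions=list(lesions),
        suv_max_patient=max(les.suv_max for les in lesions),
        tmtv_cm3=sum(les.mtv_cm3 for les in lesions),
        tlg_total=sum(les.tlg for les in lesions),
        d_max_cm=compute_dmax(lesions),
    )


def quantify(
    vol: PETVolume,
    detect_suv: float = 2.5,
    min_volume_cm3: float = 0.0,
    exclusions: np.ndarray | None = None,
    threshold_fraction: float = 0.41,
) -> PatientPET:
    """Full per-patient pipeline: detect, delineate at 41%, apply the
    bone-marrow focality rule when a marrow label is present, aggregate."""
    cands = detect_lesions(vol, detect_suv, min_volume_cm3, exclusions)
    lesions = [delineate_41(vol, c, threshold_fraction) for c in cands]
    if vol.labels is not None:
        lesions = bone_marrow_filter(lesions, vol.labels == LABEL_BONE_MARROW)
        for les in lesions:
            if vol.labels[les.peak_index] == LABEL_SPLEEN:
                les.organ_tag = "spleen"
    return summarize_patient(lesions)
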