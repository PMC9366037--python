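"""Unit tests for SUV conversion, lesion detection/delineation, organ rules
and patient-level aggregation."""

import numpy as np
import pytest

from petstrat import (
    PETVolume,
    bone_marrow_filter,
    compute_dmax,
    delineate_41,
    detect_lesions,
    spleen_involved,
    summarize_patient,
    to_suv,
)
from petstrat.petquant import Candidate, quantify


def _brute_force_components(above: np.ndarray) -> list[set]:
    """Independent 26-connectivity flood fill."""
    shape = above.shape
    seen = np.zeros(shape, dtype=bool)
    comps = []
    offsets = [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if (dx, dy, dz) != (0, 0, 0)
    ]
    for start in map(tuple, np.argwhere(above)):
        if seen[start]:
            continue
        stack, comp = [start], set()
        seen[start] = True
        while stack:
            v = stack.pop()
            comp.add(v)
            for off in offsets:
                w = tuple(a + b for a, b in zip(v, off))
                if all(0 <= w[i] < shape[i] for i in range(3)):
                    if above[w] and not seen[w]:
                        seen[w] = True
                        stack.append(w)
        comps.append(comp)
    return comps


class TestToSuv:
    def test_uniform_activity(self):
        act = np.full((4, 4, 4), 5000.0)
        vol = to_suv(act, 185.0, 70.0)
        assert vol.values == pytest.approx(5000.0 / (185e6 / 70e3))
        assert vol.values.flat[0] == pytest.approx(1.892, abs=1e-3)

    def test_zero_activity_and_weight_linearity(self):
        act = np.full((2, 2, 2), 3000.0)
        assert to_suv(np.zeros((2, 2, 2)), 185, 70).values.max() == 0.0
        v1 = to_suv(act, 185, 70).values
        v2 = to_suv(act, 185, 140).values
        np.testing.assert_allclose(v2, 2 * v1)

    @pytest.mark.parametrize("dose,weight", [(0, 70), (-1, 70), (185, 0)])
    def test_invalid_inputs(self, dose, weight):
        with pytest.raises(ValueError):
            to_suv(np.ones((2, 2, 2)), dose, weight)


class TestDetect:
    def test_single_sphere(self, sphere_phantom):
        vol, _ = sphere_phantom
        cands = detect_lesions(vol, detect_suv=2.5)
        assert len(cands) == 1

    def test_component_count_matches_flood_fill(self, multi_lesion_phantom):
        vol, _ = multi_lesion_phantom
        cands = detect_lesions(vol, detect_suv=2.5)
        oracle = _brute_force_components(vol.values >= 2.5)
        assert len(cands) == len(oracle) == 3
        got = {frozenset((int(a), int(b), int(c)) for a, b, c in np.argwhere(cand.mask))
               for cand in cands}
        want = {frozenset(comp) for comp in oracle}
        assert got == want

    def test_diagonal_touch_merges(self):
        grid = np.zeros((6, 6, 6))
        grid[1, 1, 1] = 5.0
        grid[2, 2, 2] = 4.0  # 26-neighbor of (1,1,1)
        grid[4, 4, 4] = 3.0  # isolated
        vol = PETVolume(grid, (1, 1, 1))
        cands = detect_lesions(vol, detect_suv=2.5)
        assert len(cands) == 2
        assert cands[0].n_voxels == 2  # ordered by SUVmax descending

    def test_all_below_threshold(self):
        vol = PETVolume(np.ones((5, 5, 5)), (1, 1, 1))
        assert detect_lesions(vol, detect_suv=2.5) == []

    def test_min_volume_drops_small(self):
        grid = np.zeros((8, 8, 8))
        grid[1, 1, 1] = 5.0
        grid[4:7, 4:7, 4:7] = 5.0
        vol = PETVolume(grid, (2, 2, 2))
        assert len(detect_lesions(vol, 2.5, min_volume_cm3=0.1)) == 1


class TestDelineate:
    def test_uniform_sphere_recovers_whole_component(self, sphere_phantom):
        vol, truth = sphere_phantom
        (cand,) = detect_lesions(vol, detect_suv=2.5)
        les = delineate_41(vol, cand)
        assert les.mtv_cm3 == cand.n_voxels * vol.voxel_volume_cm3
        assert les.suv_mean == 10.0
        assert les.tlg == pytest.approx(10.0 * les.mtv_cm3)
        assert les.mtv_cm3 == truth.volumes_cm3[0]

    def test_radial_falloff_matches_exhaustive_scan(self):
        # SUV falls linearly from 10 at the center to 2 at 20 mm
        shape, spacing = (40, 40, 40), (2.0, 2.0, 2.0)
        xx, yy, zz = np.meshgrid(
            *[np.arange(n) * s for n, s in zip(shape, spacing)], indexing="ij"
        )
        r = np.sqrt((xx - 40) ** 2 + (yy - 40) ** 2 + (zz - 40) ** 2)
        grid = np.where(r <= 20, 10.0 - 8.0 * r / 20.0, 0.5)
        vol = PETVolume(grid, spacing)
        (cand,) = detect_lesions(vol, detect_suv=2.0)
        les = delineate_41(vol, cand)
        thr = 0.41 * grid.max()
        oracle_n = int(((grid >= thr) & cand.mask).sum())
        assert les.n_voxels == oracle_n
        assert (vol.values[les.mask] >= 0.41 * les.suv_max).all()

    def test_tie_break_lexicographic_scan_order(self):
        grid = np.zeros((5, 5, 5))
        grid[3, 1, 2] = 7.0
        grid[1, 3, 2] = 7.0  # same z, smaller y wins
        grid[2, 2, 2] = 6.0  # connects the tied voxels
        vol = PETVolume(grid, (1, 1, 1))
        (cand,) = detect_lesions(vol, detect_suv=5.0)
        assert cand.peak_index == (3, 1, 2)

    def test_idempotent(self, sphere_phantom):
        vol, _ = sphere_phantom
        (cand,) = detect_lesions(vol, 2.5)
        les = delineate_41(vol, cand)
        again = delineate_41(
            vol, Candidate(les.mask, les.peak_index, les.suv_max)
        )
        assert (again.mask == les.mask).all()
        assert again.mtv_cm3 == les.mtv_cm3

    def test_suvmean_dominates_threshold(self, multi_lesion_phantom):
        vol, _ = multi_lesion_phantom
        for cand in detect_lesions(vol, 2.5):
            les = delineate_41(vol, cand)
            assert les.suv_mean >= 0.41 * les.suv_max


class TestOrganRules:
    def _organ_volume(self, spleen_suv, lesion=None):
        grid = np.full((20, 20, 20), 1.0)
        spleen = np.zeros_like(grid, dtype=bool)
        liver = np.zeros_like(grid, dtype=bool)
        spleen[2:8, 2:8, 2:8] = True
        liver[12:18, 12:18, 12:18] = True
        grid[spleen] = spleen_suv
        grid[liver] = 2.0
        if lesion is not None:
            grid[lesion] = 8.0
        return PETVolume(grid, (4, 4, 4)), spleen, liver

    def test_diffuse_rule_fires(self):
        vol, spleen, liver = self._organ_volume(3.2)
        res = spleen_involved(vol, spleen, liver)
        assert res.involved is True and "diffuse" in res.reason

    def test_below_150_percent_not_involved(self):
        vol, spleen, liver = self._organ_volume(2.9)
        # 2.9 < 1.5 * 2.0: diffuse rule must not fire; exclude focal hits
        res = spleen_involved(vol, spleen, liver, detect_suv=20.0)
        assert res.involved is False

    def test_focal_rule_fires_at_low_diffuse_uptake(self):
        vol, spleen, liver = self._organ_volume(1.0, lesion=(4, 4, 4))
        res = spleen_involved(vol, spleen, liver, detect_suv=2.5)
        assert res.involved is True and "focal" in res.reason

    def test_missing_mask_undetermined(self):
        vol, spleen, _ = self._organ_volume(1.0)
        res = spleen_involved(vol, spleen, None)
        assert res.involved is None

    def test_bone_marrow_focal_kept_diffuse_dropped(self, sphere_phantom):
        vol, _ = sphere_phantom
        (cand,) = detect_lesions(vol, 2.5)
        les = delineate_41(vol, cand)
        bm_small = np.zeros(vol.values.shape, dtype=bool)
        bm_small[10:35, 10:35, 10:35] = True  # lesion is a small focus inside
        kept = bone_marrow_filter([les], bm_small)
        assert len(kept) == 1 and kept[0].organ_tag == "bone_marrow"
        bm_tight = les.mask.copy()  # lesion fills the whole compartment
        assert bone_marrow_filter([delineate_41(vol, cand)], bm_tight) == []

    def test_no_mask_passthrough(self, sphere_phantom):
        vol, _ = sphere_phantom
        (cand,) = detect_lesions(vol, 2.5)
        les = delineate_41(vol, cand)
        assert bone_marrow_filter([les], None) == [les]


def _lesion_at(pos_mm, suv=5.0):
    from petstrat.petquant import Lesion

    return Lesion(
        mask=np.ones((1, 1, 1), dtype=bool),
        suv_max=suv,
        suv_mean=suv,
        mtv_cm3=1.0,
        tlg=suv,
        peak_position_mm=np.asarray(pos_mm, dtype=float),
        peak_index=(0, 0, 0),
    )


class TestDmax:
    def test_single_lesion_zero(self):
        assert compute_dmax([_lesion_at((10, 10, 10))]) == 0.0
        assert compute_dmax([]) == 0.0

    def test_3_4_5_triangle(self):
        les = [_lesion_at((0, 0, 0)), _lesion_at((300, 400, 0))]
        assert compute_dmax(les) == pytest.approx(50.0)

    def test_matches_brute_force_pairwise_max(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform(0, 500, size=(5, 3))
        les = [_lesion_at(p) for p in pts]
        brute = max(
            np.linalg.norm(pts[i] - pts[j])
            for i in range(5)
            for j in range(i + 1, 5)
        )
        assert compute_dmax(les) == pytest.approx(brute / 10.0)

    def test_translation_invariance_and_spacing_scaling(self):
        rng = np.random.default_rng(4)
        pts = rng.uniform(0, 200, size=(4, 3))
        les = [_lesion_at(p) for p in pts]
        shifted = [_lesion_at(p + 123.4) for p in pts]
        assert compute_dmax(les) == pytest.approx(compute_dmax(shifted))
        doubled = [_lesion_at(2 * p) for p in pts]
        assert compute_dmax(doubled) == pytest.approx(2 * compute_dmax(les))


class TestSummarize:
    def test_additivity(self):
        a = _lesion_at((0, 0, 0))
        b = _lesion_at((100, 0, 0))
        a.mtv_cm3, a.suv_mean, a.tlg = 10.0, 5.0, 50.0
        b.mtv_cm3, b.suv_mean, b.tlg = 20.0, 2.0, 40.0
        pat = summarize_patient([a, b])
        assert pat.tmtv_cm3 == 30.0
        assert pat.tlg_total == 90.0
        assert pat.suv_max_patient == 5.0
        # removing a lesion removes exactly its contribution
        solo = summarize_patient([a])
        assert pat.tmtv_cm3 - solo.tmtv_cm3 == b.mtv_cm3
        assert pat.tlg_total - solo.tlg_total == b.tlg

    def test_empty_lesions_all_zero(self):
        pat = summarize_patient([])
        assert pat.tmtv_cm3 == pat.tlg_total == pat.d_max_cm == 0.0

    def test_quantify_end_to_end(self, multi_lesion_phantom):
        vol, truth = multi_lesion_phantom
        pat = quantify(vol, detect_suv=2.5)
        assert len(pat.lesions) == 3
        assert pat.tmtv_cm3 == pytest.approx(truth.volumes_cm3.sum())
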