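import dataclasses

import numpy as np
import pytest

from conftest import small_spec
from sinusvol.ct_io import CTVolume
from sinusvol.phantom import CavitySpec, PhantomSpec, generate_phantom
from sinusvol.segmentation import (
    BasinCandidate,
    RuleParams,
    SegmentationFailure,
    SegmentationParams,
    basin_candidates,
    classify_air_involvement,
    morphological_open,
    propagate_sinus,
    segment_exam,
    select_sinus_basins,
    threshold_bone,
    watershed_partition,
)


class TestThresholdBone:
    def test_direct_comparison(self):
        grid = np.array([[-1000.0, 200.0], [100.0, 500.0]])
        np.testing.assert_array_equal(
            threshold_bone(grid, 150.0), np.array([[False, True], [False, True]])
        )

    def test_all_air_slice_gives_empty_mask(self):
        assert not threshold_bone(np.full((8, 8), -1000.0), 150.0).any()

    def test_boundary_value_is_bone(self):
        # the threshold itself is included (>= convention)
        assert threshold_bone(np.array([[150.0]]), 150.0)[0, 0]


def _brute_force_opening(mask: np.ndarray, radius: int) -> np.ndarray:
    """Set-theoretic opening with a digital disk, computed by enumeration."""
    offsets = [
        (dy, dx)
        for dy in range(-radius, radius + 1)
        for dx in range(-radius, radius + 1)
        if dy * dy + dx * dx <= radius * radius
    ]
    h, w = mask.shape
    eroded = np.zeros_like(mask)
    for y in range(h):
        for x in range(w):
            eroded[y, x] = all(
                0 <= y + dy < h and 0 <= x + dx < w and mask[y + dy, x + dx]
                for dy, dx in offsets
            )
    dilated = np.zeros_like(mask)
    for y in range(h):
        for x in range(w):
            if eroded[y, x]:
                for dy, dx in offsets:
                    if 0 <= y + dy < h and 0 <= x + dx < w:
                        dilated[y + dy, x + dx] = True
    return dilated


class TestMorphologicalOpen:
    def test_identity_with_zero_radius_and_area(self):
        rng = np.random.default_rng(0)
        mask = rng.random((16, 16)) > 0.5
        np.testing.assert_array_equal(
            morphological_open(mask, 0, 0.0, (0.35, 0.35)), mask
        )

    def test_isolated_pixel_erased(self):
        mask = np.zeros((9, 9), bool)
        mask[4, 4] = True
        assert not morphological_open(mask, 1, 0.0, (1.0, 1.0)).any()

    def test_negative_radius_rejected(self):
        with pytest.raises(ValueError):
            morphological_open(np.zeros((4, 4), bool), -1, 0.0, (1.0, 1.0))

    @pytest.mark.parametrize("seed", range(5))
    @pytest.mark.parametrize("radius", [1, 2])
    def test_matches_brute_force_oracle_and_idempotent(self, seed, radius):
        # interior-only content so the border convention cannot differ
        rng = np.random.default_rng(seed)
        mask = np.zeros((24, 24), bool)
        m = radius + 1
        mask[m:-m, m:-m] = rng.random((24 - 2 * m, 24 - 2 * m)) > 0.4
        opened = morphological_open(mask, radius, 0.0, (1.0, 1.0))
        expected = _brute_force_opening(mask, radius)
        np.testing.assert_array_equal(opened, expected)
        # opening is idempotent and anti-extensive
        np.testing.assert_array_equal(
            morphological_open(opened, radius, 0.0, (1.0, 1.0)), opened
        )
        assert not (opened & ~mask).any()

    def test_small_component_removal_in_mm2(self):
        mask = np.zeros((20, 20), bool)
        mask[2:4, 2:4] = True  # 4 px = 1 mm2 at 0.5 mm pixels
        mask[10:16, 10:16] = True  # 36 px = 9 mm2
        out = morphological_open(mask, 0, 5.0, (0.5, 0.5))
        assert not out[2:4, 2:4].any()
        assert out[10:16, 10:16].all()


class TestWatershedPartition:
    def test_two_wells_become_two_basins(self):
        # oracle: each connected component of HU < -500 maps 1:1 onto a basin
        sl = np.zeros((40, 60))
        sl[10:30, 8:24] = -1000.0
        sl[10:30, 36:52] = -1000.0
        sl[:, 28:32] = 400.0
        basins = watershed_partition(sl)
        from scipy import ndimage as ndi

        wells, n = ndi.label(sl < -500)
        assert n == 2
        mapped = set()
        for i in range(1, n + 1):
            ids = np.unique(basins[wells == i])
            assert len(ids) == 1
            mapped.add(int(ids[0]))
        assert len(mapped) == 2

    def test_uniform_slice_is_single_basin(self):
        basins = watershed_partition(np.full((16, 16), 40.0))
        assert len(np.unique(basins)) == 1

    def test_complete_partition_on_noisy_slice(self):
        rng = np.random.default_rng(3)
        sl = rng.normal(40, 15, (64, 64))
        sl[20:40, 20:40] = -1000
        basins = watershed_partition(sl)
        assert (basins > 0).all()  # every pixel labelled


def _cand(basin_id, area, centroid, solidity=0.9, side=None, shape=(128, 128), spacing=(0.35, 0.35)):
    mid = (shape[1] - 1) / 2.0 * spacing[1]
    side = side or ("right" if centroid[1] < mid else "left")
    return BasinCandidate(
        basin_id=basin_id, area_mm2=area, centroid_mm=centroid, solidity=solidity, side=side
    )


class TestRuleBasedSelection:
    shape = (128, 128)
    spacing = (0.35, 0.35)

    def select(self, cands, **kw):
        return select_sinus_basins(cands, RuleParams(), self.shape, self.spacing, **kw)

    def test_mirrored_pair_selected_noise_rejected(self):
        # two mirrored 600 mm2 ellipse basins plus five 5 mm2 noise basins;
        # oracle = exhaustive evaluation of every individual rule
        width = (self.shape[1] - 1) * self.spacing[1]
        right = _cand(1, 600.0, (22.0, 0.25 * width))
        left = _cand(2, 600.0, (22.0, 0.75 * width))
        noise = [_cand(10 + i, 5.0, (5.0 + i, 0.3 * width)) for i in range(5)]
        r, l = self.select([right, left] + list(noise))
        assert (r.basin_id, l.basin_id) == (1, 2)
        rules = RuleParams()
        for c in noise:
            assert c.area_mm2 < rules.min_area_mm2  # the rule that rejects them

    def test_midline_basin_rejected_by_position(self):
        width = (self.shape[1] - 1) * self.spacing[1]
        nasal = _cand(1, 600.0, (22.0, 0.5 * width))
        assert self.select([nasal]) == (None, None)

    def test_seed_symmetry_area_ratio_rejects_pair(self):
        width = (self.shape[1] - 1) * self.spacing[1]
        big = _cand(1, 600.0, (22.0, 0.75 * width))
        small = _cand(2, 150.0, (22.0, 0.25 * width))
        assert self.select([big, small]) == (None, None)
        # during propagation sides are assessed independently
        r, l = self.select([big, small], enforce_symmetry=False)
        assert (r.basin_id, l.basin_id) == (2, 1)

    def test_low_solidity_rejected(self):
        width = (self.shape[1] - 1) * self.spacing[1]
        ragged = _cand(1, 600.0, (22.0, 0.25 * width), solidity=0.3)
        assert self.select([ragged]) == (None, None)

    def test_candidates_from_partition_carry_geometry(self):
        sl = np.zeros((40, 60))
        sl[10:30, 8:24] = -1000.0
        sl[:, 28:32] = 400.0
        basins = watershed_partition(sl)
        cands = basin_candidates(basins, (0.5, 0.5))
        total_area = sum(c.area_mm2 for c in cands)
        assert total_area == pytest.approx(40 * 60 * 0.25)


def _flat_wide_spec(**over):
    """41-slice phantom whose cavities span slices 10..30 almost wall to wall."""
    base = PhantomSpec(
        grid_shape=(41, 192, 192),
        spacing_mm=(0.5, 0.35, 0.35),
        right=CavitySpec(center_mm=(10.0, 33.4, 16.0), semi_axes_mm=(5.0, 16.0, 11.0)),
        left=CavitySpec(center_mm=(10.0, 33.4, 50.85), semi_axes_mm=(5.0, 16.0, 11.0)),
        nasal_decoy=False,
        rng_seed=11,
    )
    return dataclasses.replace(base, **over)


class TestPropagation:
    def test_covers_cavity_slice_range(self):
        vol, _ = generate_phantom(_flat_wide_spec())
        regions = propagate_sinus(vol)
        for side in ("right", "left"):
            r = regions[side]
            assert r is not None
            assert r.seed_slice == 20
            assert abs(r.z_start - 10) <= 1
            assert abs(r.z_end - 30) <= 1
            assert set(r.masks) == set(range(r.z_start, r.z_end + 1))  # contiguous
            assert all(m.any() for m in r.masks.values())

    def test_pure_soft_tissue_fails(self):
        rng = np.random.default_rng(0)
        hu = rng.normal(40, 15, (20, 64, 64)).astype(np.float32)
        vol = CTVolume(voxels=hu, spacing_mm=(0.5, 0.35, 0.35))
        with pytest.raises(SegmentationFailure):
            propagate_sinus(vol)

    def test_single_left_cavity_recovered(self):
        spec = small_spec(right=dataclasses.replace(small_spec().right, present=False))
        vol, truth = generate_phantom(spec)
        regions = propagate_sinus(vol)
        assert regions["right"] is None
        assert regions["left"] is not None
        assert "right" not in truth.cavity_cm3


class TestClassification:
    def test_band_membership(self):
        # three region voxels at -800 / -50 / 30 HU -> 1 air, 2 involvement
        hu = np.full((3, 2, 2), 40.0, np.float32)
        hu[1, 0, 0], hu[1, 0, 1], hu[1, 1, 0] = -800.0, -50.0, 30.0
        vol = CTVolume(voxels=hu, spacing_mm=(1, 1, 1))
        from sinusvol.segmentation import SinusRegion3D

        mask = np.zeros((2, 2), bool)
        mask[0, 0] = mask[0, 1] = mask[1, 0] = True
        region = SinusRegion3D(side="right", seed_slice=1, masks={1: mask})
        air, inv = classify_air_involvement(region, vol)
        assert air.sum() == 1 and inv.sum() == 2

    def test_bone_and_below_band_excluded(self):
        hu = np.full((3, 2, 2), 40.0, np.float32)
        hu[1, 0, 0], hu[1, 0, 1] = 300.0, -1500.0
        vol = CTVolume(voxels=hu, spacing_mm=(1, 1, 1))
        from sinusvol.segmentation import SinusRegion3D

        region = SinusRegion3D(side="left", seed_slice=1, masks={1: np.ones((2, 2), bool)})
        air, inv = classify_air_involvement(region, vol)
        assert air.sum() == 0 and inv.sum() == 2  # the two 40 HU voxels

    def test_fully_aerated_sinus_has_zero_involvement(self, small_segmentation):
        labels, _ = small_segmentation
        from sinusvol.volumetry import compute_volumes

        for m in compute_volumes(labels):
            assert m.involvement_fraction == 0.0

    def test_air_count_monotone_in_band_upper_edge(self, small_phantom):
        vol, _ = small_phantom
        regions = propagate_sinus(vol)
        region = regions["right"]
        counts = []
        for hi in (-600.0, -400.0, -200.0, -50.0, 100.0):
            p = SegmentationParams(air_hu_high=hi)
            air, _ = classify_air_involvement(region, vol, p)
            counts.append(int(air.sum()))
        assert counts == sorted(counts)

    def test_mucosal_lining_measured_within_ten_percent(self):
        spec = small_spec(mucosa_thickness_mm=2.0, hu_mucosa=40.0, rng_seed=13)
        vol, truth = generate_phantom(spec)
        labels, _ = segment_exam(vol)
        from sinusvol.volumetry import compute_volumes

        for m in compute_volumes(labels):
            analytic_shell = truth.involvement_cm3[m.side]
            assert m.involvement_volume_cm3 == pytest.approx(analytic_shell, rel=0.10)


class TestPipelineInvariants:
    def test_air_and_involvement_disjoint_within_region(self, small_phantom):
        vol, _ = small_phantom
        regions = propagate_sinus(vol)
        for side, region in regions.items():
            air, inv = classify_air_involvement(region, vol)
            assert not (air & inv).any()
            region_voxels = np.zeros(vol.shape, bool)
            for z, m in region.masks.items():
                region_voxels[z] = m
            assert ((air | inv) & ~region_voxels).sum() == 0

    def test_mirror_symmetry_of_reflected_phantom(self, small_phantom, small_segmentation):
        vol, _ = small_phantom
        labels, _ = small_segmentation
        flipped = CTVolume(voxels=vol.voxels[:, :, ::-1].copy(), spacing_mm=vol.spacing_mm)
        flabels, _ = segment_exam(flipped)

        def counts(lab):
            return {c: int((lab.labels == c).sum()) for c in (1, 2, 3, 4)}

        c, f = counts(labels), counts(flabels)
        # side swap: right(1,2) <-> left(3,4); watershed tie-breaks at the basin
        # rim may move a handful of boundary voxels, hence the 0.5 % slack
        for a, b in ((1, 3), (2, 4)):
            assert f[b] == pytest.approx(c[a], rel=5e-3, abs=2)
            assert f[a] == pytest.approx(c[b], rel=5e-3, abs=2)

    def test_noise_free_phantom_volume_within_three_percent(self):
        vol, truth = generate_phantom(small_spec(noise_sd_hu=0.0))
        labels, _ = segment_exam(vol)
        from sinusvol.volumetry import compute_volumes

        for m in compute_volumes(labels):
            assert m.total_volume_cm3 == pytest.approx(truth.cavity_cm3[m.side], rel=0.03)
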