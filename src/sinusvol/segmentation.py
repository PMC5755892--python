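"""Hybrid per-slice segmentation of the maxillary sinuses.

The pipeline mirrors a classic hybrid CT workflow, run independently on each
axial slice:

1. threshold at the bone attenuation (default 150 HU) to expose the bony
   sinus walls;
2. morphological opening plus small-component removal to suppress noise
   specks in the bone mask;
3. watershed of the (smoothed) HU landscape into a complete partition of
   basins — air cavities are deep basins, bone walls are ridges;
4. a rule-based system on basin position, shape and symmetry that keeps only
   the maxillary sinus basin on each side.

Starting from the middle slice, the accepted regions are propagated slice by
slice in both directions until the rules are no longer satisfied, producing a
volumetric region per side.  Voxels inside a region are finally banded by HU
into air (default −1200…−200 HU) versus involvement (mucosal thickening,
cysts, fluid: −200 HU up to the bone threshold).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.measure import regionprops
from skimage.morphology import disk, local_minima, opening, reconstruction
from skimage.segmentation import watershed

from .ct_io import CTVolume, LabelMap

log = logging.getLogger(__name__)

RIGHT = "right"
LEFT = "left"
SIDES = (RIGHT, LEFT)


class SegmentationFailure(RuntimeError):
    """No sinus could be located anywhere in the seed-slice search window."""


class ParameterError(ValueError):
    pass


@dataclass(frozen=True)
class RuleParams:
    """Thresholds of the rule-based basin selection.

    Position rules are expressed as fractions of the image extent so they
    transfer across matrix sizes; the symmetry rules compare the two sides'
    candidates on the seed slice only.
    """

    min_area_mm2: float = 50.0
    max_area_mm2: float = 3000.0
    min_solidity: float = 0.6
    lateral_band: tuple[float, float] = (0.05, 0.45)
    axial_band: tuple[float, float] = (0.25, 0.85)
    symmetry_area_ratio_max: float = 3.0
    symmetry_centroid_tol_mm: float = 15.0

    def __post_init__(self) -> None:
        if not self.min_area_mm2 < self.max_area_mm2:
            raise ParameterError("min_area_mm2 must be < max_area_mm2")
        if not 0.0 <= self.min_solidity <= 1.0:
            raise ParameterError("min_solidity must be in [0, 1]")
        if self.symmetry_area_ratio_max < 1.0:
            raise ParameterError("symmetry_area_ratio_max must be >= 1")


@dataclass(frozen=True)
class SegmentationParams:
    bone_threshold_hu: float = 150.0
    opening_radius_px: int = 2
    min_component_area_mm2: float = 20.0
    air_hu_low: float = -1200.0
    air_hu_high: float = -200.0
    smoothing_sigma_px: float = 1.0
    min_basin_depth_hu: float = 100.0
    overlap_min_dice: float = 0.3
    rule_params: RuleParams = field(default_factory=RuleParams)

    def __post_init__(self) -> None:
        if not self.air_hu_low < self.air_hu_high < self.bone_threshold_hu:
            raise ParameterError("need air_hu_low < air_hu_high < bone_threshold_hu")
        if self.opening_radius_px < 0:
            raise ParameterError("opening_radius_px must be >= 0")
        if not 0.0 <= self.overlap_min_dice <= 1.0:
            raise ParameterError("overlap_min_dice must be in [0, 1]")


@dataclass(frozen=True)
class BasinCandidate:
    """One watershed basin of one slice, with the features the rules use."""

    basin_id: int
    area_mm2: float
    centroid_mm: tuple[float, float]  # (row, column)
    solidity: float
    side: str

    def __post_init__(self) -> None:
        if self.area_mm2 <= 0:
            raise ParameterError("basin area must be positive")
        if not 0 < self.solidity <= 1.0 + 1e-9:
            raise ParameterError("solidity must be in (0, 1]")


@dataclass
class SinusRegion3D:
    """Per-slice pixel masks of one sinus over a contiguous slice interval."""

    side: str
    seed_slice: int
    masks: dict[int, np.ndarray]  # slice index -> 2-D boolean mask

    @property
    def z_start(self) -> int:
        return min(self.masks)

    @property
    def z_end(self) -> int:
        return max(self.masks)

    def n_pixels(self) -> int:
        return int(sum(m.sum() for m in self.masks.values()))


# ---------------------------------------------------------------------------
# per-slice steps

def threshold_bone(slice_hu: np.ndarray, bone_threshold_hu: float = 150.0) -> np.ndarray:
    """Binary bone mask: HU >= threshold (boundary voxels are bone)."""
    return np.asarray(slice_hu) >= bone_threshold_hu


def morphological_open(
    mask: np.ndarray,
    opening_radius_px: int,
    min_component_area_mm2: float,
    spacing_mm: tuple[float, float],
) -> np.ndarray:
    """Opening with a disk element, then removal of small components.

    ``spacing_mm`` is the in-plane (row, column) spacing used to convert the
    component-area threshold from mm² to pixels.
    """
    if opening_radius_px < 0:
        raise ParameterError("opening radius must be >= 0")
    mask = np.asarray(mask, dtype=bool)
    if opening_radius_px > 0:
        mask = opening(mask, disk(opening_radius_px)).astype(bool)
    if min_component_area_mm2 > 0:
        px_area = float(spacing_mm[0]) * float(spacing_mm[1])
        lab, n = ndi.label(mask)
        if n:
            areas = ndi.sum_labels(np.ones_like(mask, dtype=np.int64), lab, np.arange(1, n + 1))
            keep = np.flatnonzero(areas * px_area >= min_component_area_mm2) + 1
            mask = np.isin(lab, keep)
    return mask


def watershed_partition(
    slice_hu: np.ndarray,
    cleaned_bone_mask: np.ndarray | None = None,
    smoothing_sigma_px: float = 1.0,
    min_basin_depth_hu: float = 100.0,
) -> np.ndarray:
    """Complete watershed partition of one slice into basins.

    The flooding surface is the Gaussian-smoothed HU image with the cleaned
    bone mask raised far above any tissue value so bone acts as ridges.
    Regional minima shallower than ``min_basin_depth_hu`` are suppressed by
    morphological reconstruction before the markers are extracted, so imaging
    noise does not fragment a cavity (or the background) into many basins.
    Every pixel receives exactly one basin label.
    """
    surface = np.asarray(slice_hu, dtype=np.float64)
    if smoothing_sigma_px > 0:
        surface = ndi.gaussian_filter(surface, smoothing_sigma_px)
    if cleaned_bone_mask is not None and cleaned_bone_mask.any():
        surface = np.where(cleaned_bone_mask, surface.max() + 2000.0, surface)
    if min_basin_depth_hu > 0:
        surface = reconstruction(surface + min_basin_depth_hu, surface, method="erosion")
    markers, _ = ndi.label(local_minima(surface, connectivity=2))
    return watershed(surface, markers)


def basin_candidates(
    basin_labels: np.ndarray, spacing_mm: tuple[float, float]
) -> list[BasinCandidate]:
    """Measure every basin of a slice partition for the rule-based system.

    The side is assigned by the basin centroid relative to the sagittal
    midline of the image, radiological convention: columns left of the
    midline are the patient's right.
    """
    sy, sx = float(spacing_mm[0]), float(spacing_mm[1])
    n_cols = basin_labels.shape[1]
    mid_col_mm = (n_cols - 1) / 2.0 * sx
    out = []
    for prop in regionprops(basin_labels):
        r_px, c_px = prop.centroid
        centroid_mm = (r_px * sy, c_px * sx)
        out.append(
            BasinCandidate(
                basin_id=int(prop.label),
                area_mm2=float(prop.area) * sy * sx,
                centroid_mm=centroid_mm,
                solidity=float(prop.solidity),
                side=RIGHT if centroid_mm[1] < mid_col_mm else LEFT,
            )
        )
    return out


def _passes_individual_rules(
    cand: BasinCandidate,
    rules: RuleParams,
    image_shape: tuple[int, int],
    spacing_mm: tuple[float, float],
) -> bool:
    if not rules.min_area_mm2 <= cand.area_mm2 <= rules.max_area_mm2:
        return False
    if cand.solidity < rules.min_solidity:
        return False
    height_mm = (image_shape[0] - 1) * float(spacing_mm[0])
    width_mm = (image_shape[1] - 1) * float(spacing_mm[1])
    row_frac = cand.centroid_mm[0] / height_mm if height_mm else 0.0
    col_frac = cand.centroid_mm[1] / width_mm if width_mm else 0.0
    if not rules.axial_band[0] <= row_frac <= rules.axial_band[1]:
        return False
    lo, hi = rules.lateral_band
    if cand.side == RIGHT:
        return lo <= col_frac <= hi
    return (1.0 - hi) <= col_frac <= (1.0 - lo)


def _survivors(
    candidates: list[BasinCandidate],
    side: str,
    rules: RuleParams,
    image_shape: tuple[int, int],
    spacing_mm: tuple[float, float],
) -> list[BasinCandidate]:
    surv = [
        c
        for c in candidates
        if c.side == side and _passes_individual_rules(c, rules, image_shape, spacing_mm)
    ]
    # largest area first; ties broken by smallest basin id (raster order)
    surv.sort(key=lambda c: (-c.area_mm2, c.basin_id))
    return surv


def select_sinus_basins(
    candidates: list[BasinCandidate],
    rule_params: RuleParams,
    image_shape: tuple[int, int],
    spacing_mm: tuple[float, float],
    enforce_symmetry: bool = True,
) -> tuple[BasinCandidate | None, BasinCandidate | None]:
    """Pick the maxillary-sinus basin per side, or ``None``.

    Candidates failing any individual rule (area bounds, solidity, lateral
    and axial position bands) are discarded; the largest survivor per side
    wins.  When ``enforce_symmetry`` is set (seed slices) and both sides have
    a survivor, the pair must additionally satisfy the area-ratio and
    mirrored-centroid symmetry rules or both sides are rejected.
    """
    best = {
        side: (surv[0] if (surv := _survivors(candidates, side, rule_params, image_shape, spacing_mm)) else None)
        for side in SIDES
    }
    right, left = best[RIGHT], best[LEFT]
    if enforce_symmetry and right is not None and left is not None:
        ratio = max(right.area_mm2, left.area_mm2) / min(right.area_mm2, left.area_mm2)
        width_mm = (image_shape[1] - 1) * float(spacing_mm[1])
        mirrored_right = (right.centroid_mm[0], width_mm - right.centroid_mm[1])
        dist = float(np.hypot(
            mirrored_right[0] - left.centroid_mm[0],
            mirrored_right[1] - left.centroid_mm[1],
        ))
        if ratio > rule_params.symmetry_area_ratio_max or dist > rule_params.symmetry_centroid_tol_mm:
            return None, None
    return right, left


# ---------------------------------------------------------------------------
# 3-D propagation

def _dice(a: np.ndarray, b: np.ndarray) -> float:
    inter = np.logical_and(a, b).sum()
    denom = a.sum() + b.sum()
    return 2.0 * inter / denom if denom else 0.0


def _process_slice(volume: CTVolume, z: int, params: SegmentationParams):
    sl = volume.voxels[z]
    in_plane = (volume.spacing_mm[1], volume.spacing_mm[2])
    bone = threshold_bone(sl, params.bone_threshold_hu)
    bone = morphological_open(
        bone, params.opening_radius_px, params.min_component_area_mm2, in_plane
    )
    basins = watershed_partition(
        sl, bone, params.smoothing_sigma_px, params.min_basin_depth_hu
    )
    return basins, basin_candidates(basins, in_plane)


def _seed_order(n_slices: int) -> list[int]:
    mid = n_slices // 2
    window = int(round(0.25 * n_slices))
    order = [mid]
    for off in range(1, window + 1):
        if mid + off < n_slices:
            order.append(mid + off)
        if mid - off >= 0:
            order.append(mid - off)
    return order


def propagate_sinus(
    volume: CTVolume, params: SegmentationParams | None = None
) -> dict[str, SinusRegion3D | None]:
    """Assemble 3-D sinus regions by propagating from the middle slice.

    The per-slice pipeline is applied to the middle slice; if neither side is
    accepted there, neighbouring slices are tried outward up to ±25 % of the
    stack.  From the seed slice each side is walked upward and downward
    independently: a new slice's basin is accepted when it passes the
    individual rules and overlaps the previous accepted mask with a Dice
    coefficient of at least ``overlap_min_dice``; the first failing slice
    stops that direction.
    """
    params = params or SegmentationParams()
    n = volume.shape[0]
    shape2d = volume.shape[1:]
    in_plane = (volume.spacing_mm[1], volume.spacing_mm[2])
    cache: dict[int, tuple[np.ndarray, list[BasinCandidate]]] = {}

    def process(z: int):
        if z not in cache:
            cache[z] = _process_slice(volume, z, params)
        return cache[z]

    seed_z = None
    seed_pick: dict[str, BasinCandidate | None] = {}
    for z in _seed_order(n):
        _, cands = process(z)
        right, left = select_sinus_basins(
            cands, params.rule_params, shape2d, in_plane, enforce_symmetry=True
        )
        if right is not None or left is not None:
            seed_z = z
            seed_pick = {RIGHT: right, LEFT: left}
            break
    if seed_z is None:
        raise SegmentationFailure(
            f"no maxillary sinus found in the seed search window "
            f"(middle slice {n // 2} ± {int(round(0.25 * n))})"
        )

    regions: dict[str, SinusRegion3D | None] = {RIGHT: None, LEFT: None}
    for side in SIDES:
        pick = seed_pick[side]
        if pick is None:
            continue
        basins, _ = process(seed_z)
        masks = {seed_z: basins == pick.basin_id}
        for step in (1, -1):
            prev = masks[seed_z]
            z = seed_z + step
            while 0 <= z < n:
                basins, cands = process(z)
                accepted = None
                for cand in _survivors(cands, side, params.rule_params, shape2d, in_plane):
                    m = basins == cand.basin_id
                    if _dice(prev, m) >= params.overlap_min_dice:
                        accepted = m
                        break
                if accepted is None:
                    break
                masks[z] = accepted
                prev = accepted
                z += step
        regions[side] = SinusRegion3D(side=side, seed_slice=seed_z, masks=masks)
    return regions


def classify_air_involvement(
    region: SinusRegion3D, volume: CTVolume, params: SegmentationParams | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Band the region's voxels into air versus involvement masks.

    Returns two 3-D boolean arrays (air, involvement).  Voxels at or above
    the bone threshold (intruding septa) or below the air band are excluded
    from both classes and therefore from the total volume.
    """
    params = params or SegmentationParams()
    air = np.zeros(volume.shape, dtype=bool)
    involvement = np.zeros(volume.shape, dtype=bool)
    for z, mask in region.masks.items():
        hu = volume.voxels[z]
        air[z] = mask & (hu >= params.air_hu_low) & (hu <= params.air_hu_high)
        involvement[z] = mask & (hu > params.air_hu_high) & (hu < params.bone_threshold_hu)
    return air, involvement


def segment_exam(
    volume: CTVolume, params: SegmentationParams | None = None
) -> tuple[LabelMap, dict[str, SinusRegion3D | None]]:
    """Full pipeline: propagate both sinuses and emit the coded label map."""
    from .ct_io import (
        LABEL_LEFT_AIR,
        LABEL_LEFT_INVOLVEMENT,
        LABEL_RIGHT_AIR,
        LABEL_RIGHT_INVOLVEMENT,
    )

    params = params or SegmentationParams()
    regions = propagate_sinus(volume, params)
    labels = np.zeros(volume.shape, dtype=np.int16)
    codes = {
        RIGHT: (LABEL_RIGHT_AIR, LABEL_RIGHT_INVOLVEMENT),
        LEFT: (LABEL_LEFT_AIR, LABEL_LEFT_INVOLVEMENT),
    }
    for side, region in regions.items():
        if region is None:
            continue
        air, involvement = classify_air_involvement(region, volume, params)
        labels[air] = codes[side][0]
        labels[involvement] = codes[side][1]
    return LabelMap(labels=labels, spacing_mm=volume.spacing_mm), regions
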