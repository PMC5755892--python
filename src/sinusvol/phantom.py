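"""Synthetic head-like CT phantoms with analytically known sinus volumes.

A phantom is a soft-tissue block containing, per side, an ellipsoidal air
cavity enclosed by a bone shell, optionally lined by mucosa and partially
filled by a dependent fluid layer, plus a midline low-attenuation "nasal
cavity" decoy channel that the rule-based selection must reject.  Cavity
membership is evaluated analytically at voxel centres, so the ground-truth
volumes (exact ellipsoid and ellipsoid-cap formulas) and the ground-truth
label map come for free, before any noise is added.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .ct_io import (
    LABEL_LEFT_AIR,
    LABEL_LEFT_INVOLVEMENT,
    LABEL_RIGHT_AIR,
    LABEL_RIGHT_INVOLVEMENT,
    CTVolume,
    LabelMap,
)


class PhantomParameterError(ValueError):
    pass


@dataclass(frozen=True)
class CavitySpec:
    """One ellipsoidal sinus cavity; axes and centre in mm, (z, y, x) order."""

    present: bool = True
    center_mm: tuple[float, float, float] = (20.0, 44.8, 20.8)
    semi_axes_mm: tuple[float, float, float] = (14.0, 16.0, 11.0)
    rotation_deg: float = 0.0  # in-plane rotation about the slice axis


def _default_right() -> CavitySpec:
    return CavitySpec(center_mm=(20.0, 44.8, 20.8))


def _default_left() -> CavitySpec:
    return CavitySpec(center_mm=(20.0, 44.8, 68.8))


@dataclass(frozen=True)
class PhantomSpec:
    grid_shape: tuple[int, int, int] = (80, 256, 256)
    spacing_mm: tuple[float, float, float] = (0.5, 0.35, 0.35)
    right: CavitySpec = field(default_factory=_default_right)
    left: CavitySpec = field(default_factory=_default_left)
    wall_thickness_mm: float = 1.5
    hu_air: float = -1000.0
    hu_soft: float = 40.0
    hu_bone: float = 700.0
    hu_mucosa: float = 30.0
    mucosa_thickness_mm: float = 0.0
    fluid_fill_fraction: float = 0.0
    noise_sd_hu: float = 15.0
    rng_seed: int = 0
    nasal_decoy: bool = True


@dataclass(frozen=True)
class PhantomTruth:
    """Analytic per-side volumes (cm³) and the exact voxelised label map."""

    cavity_cm3: dict[str, float]
    air_cm3: dict[str, float]
    involvement_cm3: dict[str, float]
    label_map: LabelMap


def _validate(spec: PhantomSpec) -> None:
    def fail(fieldname, msg):
        raise PhantomParameterError(f"{fieldname}: {msg}")

    if spec.wall_thickness_mm <= 0:
        fail("wall_thickness_mm", "must be positive")
    if not 0.0 <= spec.fluid_fill_fraction <= 1.0:
        fail("fluid_fill_fraction", "must be in [0, 1]")
    if spec.noise_sd_hu < 0:
        fail("noise_sd_hu", "must be >= 0")
    if spec.mucosa_thickness_mm < 0:
        fail("mucosa_thickness_mm", "must be >= 0")
    if not (spec.hu_air < -200.0 <= spec.hu_mucosa):
        fail("hu_air/hu_mucosa", "air must lie below -200 HU and mucosa at or above it")
    if not (spec.hu_soft < 150.0 <= spec.hu_bone):
        fail("hu_soft/hu_bone", "soft tissue must lie below 150 HU and bone at or above it")
    extent = [s * (n - 1) for s, n in zip(spec.spacing_mm, spec.grid_shape)]
    for name, cav in (("right", spec.right), ("left", spec.left)):
        if not cav.present:
            continue
        for ax in range(3):
            if cav.semi_axes_mm[ax] <= spec.wall_thickness_mm:
                fail(f"{name}.semi_axes_mm", "semi-axes must exceed the wall thickness")
            if cav.semi_axes_mm[ax] - spec.mucosa_thickness_mm <= 0:
                fail(f"{name}.semi_axes_mm", "mucosa thicker than the cavity semi-axis")
            outer = cav.semi_axes_mm[ax] + spec.wall_thickness_mm
            if ax == 0 or not cav.rotation_deg:
                reach = outer
            else:
                # rotated footprint stays inside the in-plane circumscribing radius
                reach = max(cav.semi_axes_mm[1], cav.semi_axes_mm[2]) + spec.wall_thickness_mm
            if cav.center_mm[ax] - reach < 0 or cav.center_mm[ax] + reach > extent[ax]:
                fail(f"{name}.center_mm", "cavity (including wall) does not fit in the grid")


def _ellipsoid_mask(coords, cav: CavitySpec, semi_axes) -> np.ndarray:
    dz = coords[0] - cav.center_mm[0]
    dy = coords[1] - cav.center_mm[1]
    dx = coords[2] - cav.center_mm[2]
    if cav.rotation_deg:
        th = math.radians(cav.rotation_deg)
        dy, dx = math.cos(th) * dy + math.sin(th) * dx, -math.sin(th) * dy + math.cos(th) * dx
    az, ay, ax = semi_axes
    return (dz / az) ** 2 + (dy / ay) ** 2 + (dx / ax) ** 2 <= 1.0


def _ellipsoid_volume_cm3(semi_axes) -> float:
    az, ay, ax = semi_axes
    return 4.0 / 3.0 * math.pi * az * ay * ax / 1000.0


def _cap_volume_cm3(semi_axes, h_mm: float) -> float:
    """Volume of the ellipsoid cap of height h measured from the bottom pole."""
    az, ay, ax = semi_axes
    h = min(max(h_mm, 0.0), 2.0 * az)
    return math.pi * ay * ax / az**2 * h * h * (az - h / 3.0) / 1000.0


def generate_phantom(spec: PhantomSpec | None = None) -> tuple[CTVolume, PhantomTruth]:
    """Build the HU volume and its exact ground truth.

    Truth is computed from analytic ellipsoid membership of voxel centres
    before noise; the returned volume adds seeded Gaussian HU noise on top of
    the piecewise-constant tissue classes.
    """
    spec = spec or PhantomSpec()
    _validate(spec)
    nz, ny, nx = spec.grid_shape
    sz, sy, sx = spec.spacing_mm
    zc = np.arange(nz, dtype=np.float64)[:, None, None] * sz
    yc = np.arange(ny, dtype=np.float64)[None, :, None] * sy
    xc = np.arange(nx, dtype=np.float64)[None, None, :] * sx
    coords = (zc, yc, xc)

    hu = np.full(spec.grid_shape, spec.hu_soft, dtype=np.float64)
    labels = np.zeros(spec.grid_shape, dtype=np.int16)

    if spec.nasal_decoy:
        # midline channel: elliptical cylinder along z with its own bone lining
        mid_x = (nx - 1) / 2.0 * sx
        mid_y = (ny - 1) / 2.0 * sy
        dy = yc - mid_y
        dx = xc - mid_x
        z_ok = (zc >= 0.1 * (nz - 1) * sz) & (zc <= 0.9 * (nz - 1) * sz)
        r_in = (dy / 14.0) ** 2 + (dx / 4.0) ** 2
        r_out = (dy / (14.0 + spec.wall_thickness_mm)) ** 2 + (dx / (4.0 + spec.wall_thickness_mm)) ** 2
        hu = np.where(z_ok & (r_out <= 1.0), spec.hu_bone, hu)
        hu = np.where(z_ok & (r_in <= 1.0), spec.hu_air, hu)

    codes = {"right": (LABEL_RIGHT_AIR, LABEL_RIGHT_INVOLVEMENT),
             "left": (LABEL_LEFT_AIR, LABEL_LEFT_INVOLVEMENT)}
    cavity_cm3: dict[str, float] = {}
    air_cm3: dict[str, float] = {}
    involvement_cm3: dict[str, float] = {}

    for side, cav in (("right", spec.right), ("left", spec.left)):
        if not cav.present:
            continue
        outer_axes = tuple(a + spec.wall_thickness_mm for a in cav.semi_axes_mm)
        inner_axes = tuple(a - spec.mucosa_thickness_mm for a in cav.semi_axes_mm)
        outer = _ellipsoid_mask(coords, cav, outer_axes)
        cavity = _ellipsoid_mask(coords, cav, cav.semi_axes_mm)
        core = _ellipsoid_mask(coords, cav, inner_axes)

        az_in = inner_axes[0]
        z_fluid = cav.center_mm[0] - az_in + 2.0 * az_in * spec.fluid_fill_fraction
        fluid = core & (zc < z_fluid)
        air = core & ~fluid
        involvement = cavity & ~air

        hu = np.where(outer & ~cavity, spec.hu_bone, hu)
        hu = np.where(involvement, spec.hu_mucosa, hu)
        hu = np.where(air, spec.hu_air, hu)
        labels[involvement] = codes[side][1]
        labels[air] = codes[side][0]

        cavity_cm3[side] = _ellipsoid_volume_cm3(cav.semi_axes_mm)
        v_core = _ellipsoid_volume_cm3(inner_axes)
        v_fluid = _cap_volume_cm3(inner_axes, z_fluid - (cav.center_mm[0] - az_in))
        air_cm3[side] = v_core - v_fluid
        involvement_cm3[side] = cavity_cm3[side] - air_cm3[side]

    if spec.noise_sd_hu > 0:
        rng = np.random.default_rng(spec.rng_seed)
        hu = hu + rng.normal(0.0, spec.noise_sd_hu, size=spec.grid_shape)

    volume = CTVolume(
        voxels=hu.astype(np.float32),
        spacing_mm=spec.spacing_mm,
        patient_orientation="LPS-aligned",
    )
    truth = PhantomTruth(
        cavity_cm3=cavity_cm3,
        air_cm3=air_cm3,
        involvement_cm3=involvement_cm3,
        label_map=LabelMap(labels=labels, spacing_mm=spec.spacing_mm),
    )
    return volume, truth


@dataclass(frozen=True)
class VariationRanges:
    """Uniform sampling ranges for a synthetic validation cohort.

    Defaults emulate the anatomical spread of adult maxillary sinuses at the
    phantom's grid size: per-side semi-axes drawn independently, cavity
    centres jittered, a thin-to-moderate mucosal lining everywhere, and up to
    a third of the cavity height filled with dependent fluid.
    """

    semi_axis_z_mm: tuple[float, float] = (12.0, 16.0)
    semi_axis_y_mm: tuple[float, float] = (12.0, 18.0)
    semi_axis_x_mm: tuple[float, float] = (9.0, 14.0)
    center_jitter_mm: float = 2.0
    mucosa_thickness_mm: tuple[float, float] = (0.5, 2.5)
    fluid_fill_fraction: tuple[float, float] = (0.0, 0.3)

    def __post_init__(self) -> None:
        for name in ("semi_axis_z_mm", "semi_axis_y_mm", "semi_axis_x_mm",
                     "mucosa_thickness_mm", "fluid_fill_fraction"):
            lo, hi = getattr(self, name)
            if hi < lo:
                raise PhantomParameterError(f"{name}: empty range ({lo}, {hi})")
        if self.center_jitter_mm < 0:
            raise PhantomParameterError("center_jitter_mm: must be >= 0")


def generate_cohort(
    n_exams: int,
    base_spec: PhantomSpec | None = None,
    variation_ranges: VariationRanges | None = None,
    rng_seed: int = 0,
) -> list[tuple[CTVolume, PhantomTruth]]:
    """Seeded cohort of phantoms with per-exam anatomical variation.

    Geometry is drawn from ``rng_seed``; exam ``i``'s noise seed is
    ``base_spec.rng_seed + i`` so a one-exam cohort with zero-width ranges
    reproduces ``generate_phantom(base_spec)`` exactly.
    """
    if n_exams < 1:
        raise PhantomParameterError("n_exams must be >= 1")
    base = base_spec or PhantomSpec()
    var = variation_ranges or VariationRanges()
    rng = np.random.default_rng(rng_seed)

    def u(lo, hi):
        return float(rng.uniform(lo, hi)) if hi > lo else float(lo)

    out = []
    for i in range(n_exams):
        sides = {}
        for name in ("right", "left"):
            cav = getattr(base, name)
            axes = (
                u(*var.semi_axis_z_mm),
                u(*var.semi_axis_y_mm),
                u(*var.semi_axis_x_mm),
            )
            j = var.center_jitter_mm
            center = tuple(
                c + (float(rng.uniform(-j, j)) if j > 0 else 0.0) for c in cav.center_mm
            )
            sides[name] = replace(cav, semi_axes_mm=axes, center_mm=center)
        spec = replace(
            base,
            right=sides["right"],
            left=sides["left"],
            mucosa_thickness_mm=u(*var.mucosa_thickness_mm),
            fluid_fill_fraction=u(*var.fluid_fill_fraction),
            rng_seed=base.rng_seed + i,
        )
        out.append(generate_phantom(spec))
    return out
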