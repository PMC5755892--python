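"""Physical volumes and surface meshes from sinus label maps.

Volumes are voxel counts multiplied by the voxel volume (the product of the
three spacing components); no mesh-based measurement is ever used for the
reported numbers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import trimesh
from skimage.measure import marching_cubes

from .ct_io import (
    LABEL_LEFT_AIR,
    LABEL_LEFT_INVOLVEMENT,
    LABEL_RIGHT_AIR,
    LABEL_RIGHT_INVOLVEMENT,
    InputError,
    LabelMap,
)

log = logging.getLogger(__name__)

_SIDE_CODES = {
    "right": (LABEL_RIGHT_AIR, LABEL_RIGHT_INVOLVEMENT),
    "left": (LABEL_LEFT_AIR, LABEL_LEFT_INVOLVEMENT),
}


@dataclass(frozen=True)
class SinusMeasurement:
    """Per-sinus volumetry: total = air + involvement by construction."""

    side: str
    n_voxels_air: int
    n_voxels_involvement: int
    voxel_volume_mm3: float

    @property
    def n_voxels_total(self) -> int:
        return self.n_voxels_air + self.n_voxels_involvement

    @property
    def air_volume_cm3(self) -> float:
        return self.n_voxels_air * self.voxel_volume_mm3 / 1000.0

    @property
    def involvement_volume_cm3(self) -> float:
        return self.n_voxels_involvement * self.voxel_volume_mm3 / 1000.0

    @property
    def total_volume_cm3(self) -> float:
        return self.n_voxels_total * self.voxel_volume_mm3 / 1000.0

    @property
    def involvement_fraction(self) -> float:
        return (
            self.n_voxels_involvement / self.n_voxels_total if self.n_voxels_total else 0.0
        )

    def as_dict(self) -> dict:
        return {
            "side": self.side,
            "total_cm3": round(self.total_volume_cm3, 2),
            "air_cm3": round(self.air_volume_cm3, 2),
            "involvement_cm3": round(self.involvement_volume_cm3, 2),
            "involvement_fraction": self.involvement_fraction,
            "voxel_volume_mm3": self.voxel_volume_mm3,
            "n_voxels_total": self.n_voxels_total,
            "n_voxels_air": self.n_voxels_air,
            "n_voxels_involvement": self.n_voxels_involvement,
        }


def compute_volumes(labels: LabelMap) -> list[SinusMeasurement]:
    """Measure both sinuses; a side with zero voxels is omitted with a note."""
    voxvol = float(np.prod(labels.spacing_mm))
    flat = labels.labels
    out = []
    for side, (air_code, inv_code) in _SIDE_CODES.items():
        n_air = int(np.count_nonzero(flat == air_code))
        n_inv = int(np.count_nonzero(flat == inv_code))
        if n_air + n_inv == 0:
            log.info("side %s has no labelled voxels; omitted from measurements", side)
            continue
        out.append(
            SinusMeasurement(
                side=side,
                n_voxels_air=n_air,
                n_voxels_involvement=n_inv,
                voxel_volume_mm3=voxvol,
            )
        )
    return out


def _class_mask(labels: LabelMap, class_selector: str) -> np.ndarray:
    if class_selector == "total":
        return labels.labels > 0
    if class_selector == "involvement":
        return np.isin(labels.labels, (LABEL_RIGHT_INVOLVEMENT, LABEL_LEFT_INVOLVEMENT))
    if class_selector == "air":
        return np.isin(labels.labels, (LABEL_RIGHT_AIR, LABEL_LEFT_AIR))
    raise InputError(f"unknown class selector {class_selector!r}")


def extract_surface(
    labels: LabelMap, class_selector: str = "total", smooth: bool = False
) -> trimesh.Trimesh:
    """Closed triangulated isosurface of a label class, vertices in mm.

    The isosurface is taken at the 0.5 level of the binary class mask with
    marching-cubes topology; the mask is zero-padded first so the surface is
    watertight even when the class touches the grid boundary.  Optional
    Laplacian smoothing is for display only.
    """
    mask = _class_mask(labels, class_selector)
    if not mask.any():
        raise InputError(f"class {class_selector!r} selects no voxels")
    padded = np.pad(mask.astype(np.float32), 1)
    verts, faces, _, _ = marching_cubes(padded, level=0.5, spacing=labels.spacing_mm)
    verts -= np.asarray(labels.spacing_mm)  # undo the one-voxel pad offset
    # flip winding so face normals point outward (positive enclosed volume)
    mesh = trimesh.Trimesh(vertices=verts, faces=faces[:, ::-1], process=False)
    if smooth:
        trimesh.smoothing.filter_laplacian(mesh, iterations=5)
    return mesh


def save_surface(mesh: trimesh.Trimesh, file_path) -> None:
    """Write the mesh as PLY or STL, by file extension."""
    mesh.export(str(file_path))
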