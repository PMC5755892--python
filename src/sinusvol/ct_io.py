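"""Reading and writing CT volumes and label maps.

The in-memory convention throughout the package is a 3-D array ordered
``(slice, row, column)`` with slice index 0 the most inferior slice when
orientation metadata allows that to be determined.  All geometry is in
millimetres and voxel values are calibrated Hounsfield Units.

Label maps use the integer codes::

    0  background
    1  right sinus, air
    2  right sinus, involvement
    3  left sinus, air
    4  left sinus, involvement
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

log = logging.getLogger(__name__)

HU_MIN = -2048.0
HU_MAX = 4096.0

LABEL_BACKGROUND = 0
LABEL_RIGHT_AIR = 1
LABEL_RIGHT_INVOLVEMENT = 2
LABEL_LEFT_AIR = 3
LABEL_LEFT_INVOLVEMENT = 4
VALID_LABELS = frozenset(range(5))


class InputError(ValueError):
    """Raised for malformed or unsupported input data."""


class GeometryError(InputError):
    """Raised when spatial metadata is missing or contradictory."""


@dataclass(frozen=True)
class CTVolume:
    """A calibrated HU voxel grid with physical geometry.

    Parameters
    ----------
    voxels
        3-D float array of Hounsfield Units, axis order (slice, row, column).
    spacing_mm
        Voxel spacing (between-slice, row, column) in mm; all positive.
    origin_mm
        Position of voxel (0, 0, 0) in mm.
    patient_orientation
        ``"LPS-aligned"`` when the axes are known to follow the scanner
        patient coordinate convention, otherwise ``"unknown"``.
    """

    voxels: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    patient_orientation: str = "unknown"
    slice_axis: int = 0

    def __post_init__(self) -> None:
        v = np.asarray(self.voxels)
        if v.ndim != 3:
            raise InputError(f"expected a 3-D volume, got ndim={v.ndim}")
        if v.shape[0] < 3:
            raise InputError(
                f"need at least 3 slices (middle slice and neighbours), got {v.shape[0]}"
            )
        if any(s <= 0 for s in self.spacing_mm):
            raise GeometryError(f"spacing must be positive, got {self.spacing_mm}")
        if v.size and (v.min() < HU_MIN or v.max() > HU_MAX):
            raise InputError(
                f"HU values outside calibrated range [{HU_MIN}, {HU_MAX}]: "
                f"[{v.min():.1f}, {v.max():.1f}]"
            )
        if self.patient_orientation not in ("LPS-aligned", "unknown"):
            raise InputError(f"bad patient_orientation {self.patient_orientation!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[self.slice_axis]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))


@dataclass(frozen=True)
class LabelMap:
    """Integer label volume congruent with a :class:`CTVolume`."""

    labels: np.ndarray
    spacing_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim != 3:
            raise InputError("label map must be 3-D")
        if not np.issubdtype(lab.dtype, np.integer):
            raise InputError("label map must have an integer dtype")
        present = set(np.unique(lab).tolist())
        if not present <= VALID_LABELS:
            raise InputError(f"labels outside {sorted(VALID_LABELS)}: {sorted(present - VALID_LABELS)}")
        if any(s <= 0 for s in self.spacing_mm):
            raise GeometryError(f"spacing must be positive, got {self.spacing_mm}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape


# ---------------------------------------------------------------------------
# NIfTI

def _to_xyz(voxels: np.ndarray) -> np.ndarray:
    # (slice,row,col) -> (x,y,z) for the NIfTI on-disk layout
    return np.ascontiguousarray(np.transpose(voxels, (2, 1, 0)))


def _from_xyz(data: np.ndarray) -> np.ndarray:
    return np.ascontiguousarray(np.transpose(data, (2, 1, 0)))


def _affine(spacing_zyx, origin_zyx) -> np.ndarray:
    sz, sy, sx = spacing_zyx
    oz, oy, ox = origin_zyx
    aff = np.diag([sx, sy, sz, 1.0])
    aff[:3, 3] = [ox, oy, oz]
    return aff


def write_nifti(volume: CTVolume, file_path) -> None:
    """Write a CT volume as a float32 NIfTI image."""
    img = nib.Nifti1Image(
        _to_xyz(volume.voxels.astype(np.float32)),
        _affine(volume.spacing_mm, volume.origin_mm),
    )
    nib.save(img, str(file_path))


def read_nifti(file_path) -> CTVolume:
    """Read a 3-D HU-calibrated NIfTI image.

    Axis order is normalised to (slice, row, column); spacing comes from the
    header zooms.  4-D or non-scalar images are rejected.
    """
    img = nib.load(str(file_path))
    if len(img.shape) != 3:
        raise InputError(f"expected a 3-D scalar image, got shape {img.shape}")
    data = np.asanyarray(img.dataobj)
    if data.dtype.kind not in "fiu":
        raise InputError(f"non-scalar voxel dtype {data.dtype}")
    zooms = img.header.get_zooms()[:3]
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    aff = img.affine
    # axis-aligned affine (as produced by this package's writers) implies a
    # known patient orientation; anything else is treated as unknown
    ortho = np.allclose(aff[:3, :3], np.diag(np.diag(aff[:3, :3])), atol=1e-6)
    orientation = "LPS-aligned" if ortho and np.all(np.diag(aff[:3, :3]) > 0) else "unknown"
    origin = (float(aff[2, 3]), float(aff[1, 3]), float(aff[0, 3]))
    return CTVolume(
        voxels=_from_xyz(data).astype(np.float32),
        spacing_mm=spacing,
        origin_mm=origin,
        patient_orientation=orientation,
    )


def write_label_map(labels: LabelMap, file_path, reference: CTVolume | None = None) -> None:
    """Write a label map as an int16 NIfTI image (lossless round trip)."""
    if reference is not None and labels.shape != reference.shape:
        raise InputError(
            f"label shape {labels.shape} does not match reference volume {reference.shape}"
        )
    img = nib.Nifti1Image(
        _to_xyz(labels.labels.astype(np.int16)),
        _affine(labels.spacing_mm, (0.0, 0.0, 0.0)),
    )
    nib.save(img, str(file_path))


def read_label_map(file_path) -> LabelMap:
    img = nib.load(str(file_path))
    if len(img.shape) != 3:
        raise InputError(f"expected a 3-D label image, got shape {img.shape}")
    data = np.asanyarray(img.dataobj)
    zooms = img.header.get_zooms()[:3]
    return LabelMap(
        labels=_from_xyz(np.rint(data).astype(np.int16)),
        spacing_mm=(float(zooms[2]), float(zooms[1]), float(zooms[0])),
    )


# ---------------------------------------------------------------------------
# DICOM

_MAX_GAP_VARIATION = 0.05  # tolerated relative spread of inter-slice gaps


def read_dicom_series(directory_path) -> CTVolume:
    """Read a single-frame CT DICOM series from a directory.

    Slices are sorted by spatial position along the slice normal (never by
    filename), stored values are converted to HU with the modality rescale
    transform ``HU = slope * stored + intercept``, and spacing is taken from
    PixelSpacing plus the mean inter-slice distance.
    """
    directory = Path(directory_path)
    paths = sorted(p for p in directory.iterdir() if p.is_file())
    datasets = []
    for p in paths:
        try:
            ds = pydicom.dcmread(str(p))
        except Exception:
            continue
        if hasattr(ds, "PixelData"):
            datasets.append(ds)
    if len(datasets) < 3:
        raise InputError(f"found {len(datasets)} image slices in {directory}; need >= 3")

    uids = {getattr(ds, "SeriesInstanceUID", None) for ds in datasets}
    if len(uids) != 1:
        raise InputError(f"mixed series in one directory: {len(uids)} SeriesInstanceUIDs")
    modalities = {getattr(ds, "Modality", "") for ds in datasets}
    if modalities != {"CT"}:
        raise InputError(f"non-CT modality in series: {sorted(modalities)}")

    ref = datasets[0]
    try:
        iop = np.asarray(ref.ImageOrientationPatient, dtype=float)
        row_dir, col_dir = iop[:3], iop[3:]
        normal = np.cross(row_dir, col_dir)
    except Exception as exc:
        raise GeometryError(f"missing ImageOrientationPatient: {exc}") from exc

    def position(ds):
        try:
            return float(np.dot(np.asarray(ds.ImagePositionPatient, dtype=float), normal))
        except Exception as exc:
            raise GeometryError(f"missing ImagePositionPatient: {exc}") from exc

    datasets.sort(key=position)
    positions = np.array([position(ds) for ds in datasets])
    gaps = np.diff(positions)
    if np.any(gaps <= 0):
        raise GeometryError("duplicate or non-monotonic slice positions")
    mean_gap = float(gaps.mean())
    if (gaps.max() - gaps.min()) / mean_gap > _MAX_GAP_VARIATION:
        raise GeometryError(
            f"inter-slice gap varies by more than {_MAX_GAP_VARIATION:.0%}: "
            f"[{gaps.min():.4f}, {gaps.max():.4f}] mm"
        )

    try:
        ps = [float(x) for x in ref.PixelSpacing]
    except Exception as exc:
        raise GeometryError(f"missing PixelSpacing: {exc}") from exc

    slices = []
    for ds in datasets:
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        slices.append(ds.pixel_array.astype(np.float32) * slope + intercept)
    voxels = np.clip(np.stack(slices, axis=0), HU_MIN, HU_MAX)

    origin = np.asarray(datasets[0].ImagePositionPatient, dtype=float)
    return CTVolume(
        voxels=voxels,
        spacing_mm=(mean_gap, ps[0], ps[1]),
        origin_mm=(float(origin[2]), float(origin[1]), float(origin[0])),
        patient_orientation="LPS-aligned",
    )


def write_dicom_series(volume: CTVolume, directory_path, series_uid: str | None = None) -> None:
    """Write a CT volume as a minimal single-frame DICOM series.

    Stored values are int16 with rescale slope 1 / intercept −1024, so the
    round trip through :func:`read_dicom_series` is exact up to integer
    quantisation of the HU values.
    """
    directory = Path(directory_path)
    directory.mkdir(parents=True, exist_ok=True)
    series_uid = series_uid or generate_uid()
    study_uid = generate_uid()
    intercept = -1024.0
    sz, sy, sx = volume.spacing_mm
    for i in range(volume.shape[0]):
        stored = np.rint(volume.voxels[i] - intercept).astype(np.int16)
        ds = Dataset()
        ds.file_meta = FileMetaDataset()
        ds.file_meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds.file_meta.MediaStorageSOPClassUID = pydicom.uid.CTImageStorage
        ds.file_meta.MediaStorageSOPInstanceUID = generate_uid()
        ds.SOPClassUID = pydicom.uid.CTImageStorage
        ds.SOPInstanceUID = ds.file_meta.MediaStorageSOPInstanceUID
        ds.Modality = "CT"
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.InstanceNumber = i + 1
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.ImagePositionPatient = [
            volume.origin_mm[2],
            volume.origin_mm[1],
            volume.origin_mm[0] + i * sz,
        ]
        ds.PixelSpacing = [sy, sx]
        ds.SliceThickness = sz
        ds.RescaleSlope = 1.0
        ds.RescaleIntercept = intercept
        ds.Rows, ds.Columns = stored.shape
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 1
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.PixelData = stored.tobytes()
        ds.save_as(str(directory / f"slice_{i:04d}.dcm"), enforce_file_format=True)
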