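"""Geometry-aware volume/mask data model and file I/O.

The package-wide axis convention is a fixed (axial, coronal, sagittal) index
order: ``data[a0, a1, a2]`` with 0-based indices and half-open voxel ranges.
``spacing[i]`` is the physical step in millimetres along array axis ``i``.
For single-tooth volumes axis 0 is the tooth long axis.

Spacing and origin are quantized to 32-bit float precision on construction.
This matches the precision of the NIfTI-1 header (pixdim/srow are float32)
and guarantees that geometry metadata survives write/read round trips
bit-exactly for both NIfTI and NRRD.

DICOM series are read-only; NIfTI is the internal interchange format.
Intensities are stored as floating point after read.  No HU calibration is
attempted: CBCT grey values are not Hounsfield units.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np
import pydicom
import SimpleITK as sitk
from scipy import ndimage

from .errors import DomainError, GeometryError

__all__ = [
    "VoxelVolume",
    "BinaryMask",
    "ToothEntry",
    "ScaleRecord",
    "read_volume",
    "write_volume",
    "resample_isotropic",
    "resize_to_shape",
    "invert_resize",
    "dice",
    "TOOTH_CONDITIONS",
    "valid_fdi_codes",
]

AXIS_ORDER = "ACS"  # axial, coronal, sagittal index order

TOOTH_CONDITIONS = ("intact", "missing", "restorated", "support", "excluded")


def _quantize(vec) -> tuple[float, float, float]:
    """Round a length-3 float vector through float32, back to Python floats."""
    arr = np.asarray(vec, dtype=np.float32).astype(float)
    if arr.shape != (3,):
        raise ValueError(f"expected a length-3 vector, got shape {arr.shape}")
    return tuple(arr)


@dataclass(frozen=True)
class VoxelVolume:
    """A 3D scalar grid with per-axis voxel spacing in millimetres."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_order: str = AXIS_ORDER

    def __post_init__(self):
        data = np.asarray(self.data)
        if data.ndim != 3 or min(data.shape) < 1:
            raise ValueError(f"volume data must be 3D with positive extents, got {data.shape}")
        if data.dtype != np.float32:
            data = data.astype(np.float32)
        object.__setattr__(self, "data", data)
        spacing = _quantize(self.spacing)
        if any(s <= 0 for s in spacing):
            raise ValueError(f"spacing components must be > 0, got {spacing}")
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", _quantize(self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def physical_extent(self) -> tuple[float, float, float]:
        """Per-axis extent in mm (shape x spacing)."""
        return tuple(n * s for n, s in zip(self.shape, self.spacing))

    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def with_data(self, data: np.ndarray) -> "VoxelVolume":
        return replace(self, data=data)


@dataclass(frozen=True)
class BinaryMask:
    """A 3D boolean grid sharing the spacing/origin contract of VoxelVolume."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_order: str = AXIS_ORDER

    def __post_init__(self):
        data = np.asarray(self.data)
        if data.ndim != 3 or min(data.shape) < 1:
            raise ValueError(f"mask data must be 3D with positive extents, got {data.shape}")
        if data.dtype != bool:
            uniq = np.unique(data)
            if not np.all(np.isin(uniq, (0, 1))):
                raise ValueError("mask values must be strictly two-valued (0/1)")
            data = data.astype(bool)
        object.__setattr__(self, "data", data)
        spacing = _quantize(self.spacing)
        if any(s <= 0 for s in spacing):
            raise ValueError(f"spacing components must be > 0, got {spacing}")
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", _quantize(self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def volume_mm3(self) -> float:
        return float(self.data.sum()) * float(np.prod(self.spacing))

    def matches_geometry(self, other) -> bool:
        return self.shape == other.shape and self.spacing == other.spacing

    def with_data(self, data: np.ndarray) -> "BinaryMask":
        return replace(self, data=data)


def valid_fdi_codes() -> frozenset[int]:
    """Permanent-dentition FDI two-digit codes (11-18, 21-28, 31-38, 41-48)."""
    return frozenset(10 * q + t for q in (1, 2, 3, 4) for t in range(1, 9))


_FDI = valid_fdi_codes()


@dataclass
class ToothEntry:
    """One tooth: FDI code, its segmentation mask, and its clinical condition."""

    tooth_id: int
    mask: BinaryMask
    condition: str = "intact"

    def __post_init__(self):
        self.tooth_id = int(self.tooth_id)
        if self.tooth_id not in _FDI:
            raise ValueError(f"{self.tooth_id} is not a valid FDI tooth code")
        if self.condition not in TOOTH_CONDITIONS:
            raise ValueError(
                f"condition {self.condition!r} not in {TOOTH_CONDITIONS}"
            )


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def _infer_format(path: str) -> str:
    if os.path.isdir(path):
        return "dicom_series"
    lower = path.lower()
    if lower.endswith((".nii", ".nii.gz")):
        return "nifti"
    if lower.endswith((".nrrd", ".nhdr")):
        return "nrrd"
    raise ValueError(f"cannot infer volume format from path {path!r}")


def read_volume(path: str, format: str | None = None) -> VoxelVolume:
    """Read a volume from NIfTI, NRRD, or a DICOM series directory.

    DICOM slice ordering is resolved by sorting on the slice position along
    the acquisition normal; an inconsistent slice pitch (missing/duplicated
    slice) raises :class:`GeometryError`.
    """
    if format is None:
        format = _infer_format(path)
    if format == "nifti":
        return _read_nifti(path)
    if format == "nrrd":
        return _read_nrrd(path)
    if format == "dicom_series":
        return _read_dicom_series(path)
    raise ValueError(f"unknown volume format {format!r}")


def write_volume(volume: VoxelVolume | BinaryMask, path: str) -> None:
    """Write to NIfTI or NRRD, inferred from the extension. DICOM is read-only."""
    fmt = _infer_format(path)
    data = volume.data
    if data.dtype == bool:
        data = data.astype(np.uint8)
    if fmt == "nifti":
        affine = np.diag(list(volume.spacing) + [1.0])
        affine[:3, 3] = volume.origin
        img = nib.Nifti1Image(data, affine)
        img.header.set_zooms(volume.spacing)
        nib.save(img, path)
    elif fmt == "nrrd":
        # SimpleITK's array axis order is (z, y, x) relative to image axes.
        img = sitk.GetImageFromArray(data)
        img.SetSpacing(tuple(volume.spacing[::-1]))
        img.SetOrigin(tuple(volume.origin[::-1]))
        sitk.WriteImage(img, path)
    else:
        raise ValueError(f"writing format {fmt!r} is not supported")


def _read_nifti(path: str) -> VoxelVolume:
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such volume file: {path}")
    try:
        img = nib.load(path)
    except Exception as exc:  # corrupt file
        raise OSError(f"failed to read NIfTI volume {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj).astype(np.float32)
    affine = img.affine
    spacing = np.sqrt((affine[:3, :3] ** 2).sum(axis=0))
    origin = affine[:3, 3]
    return VoxelVolume(data, tuple(spacing), tuple(origin))


def _read_nrrd(path: str) -> VoxelVolume:
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such volume file: {path}")
    try:
        img = sitk.ReadImage(path)
    except Exception as exc:
        raise OSError(f"failed to read NRRD volume {path}: {exc}") from exc
    data = sitk.GetArrayFromImage(img).astype(np.float32)
    spacing = tuple(img.GetSpacing()[::-1])
    origin = tuple(img.GetOrigin()[::-1])
    return VoxelVolume(data, spacing, origin)


def _read_dicom_series(path: str) -> VoxelVolume:
    if not os.path.isdir(path):
        raise FileNotFoundError(f"no such DICOM directory: {path}")
    files = sorted(
        os.path.join(path, f)
        for f in os.listdir(path)
        if f.lower().endswith((".dcm", ".ima")) or "." not in f
    )
    if not files:
        raise OSError(f"no DICOM files found in {path}")
    slices = []
    for f in files:
        try:
            slices.append(pydicom.dcmread(f))
        except Exception as exc:
            raise OSError(f"failed to read DICOM file {f}: {exc}") from exc
    # Sort by position along the slice normal (fall back to InstanceNumber).
    if all(hasattr(s, "ImagePositionPatient") for s in slices):
        positions = [float(s.ImagePositionPatient[2]) for s in slices]
    else:
        positions = [float(getattr(s, "InstanceNumber", i)) for i, s in enumerate(slices)]
    order = np.argsort(positions)
    slices = [slices[i] for i in order]
    positions = [positions[i] for i in order]
    if len(slices) > 1:
        steps = np.diff(positions)
        if np.any(steps <= 0):
            raise GeometryError(f"duplicate or unsorted DICOM slice positions in {path}")
        pitch = np.median(steps)
        if np.any(np.abs(steps - pitch) > 0.01 * pitch + 1e-6):
            raise GeometryError(
                f"inconsistent DICOM slice spacing in {path}: "
                f"steps range {steps.min():.4f}-{steps.max():.4f} mm (pitch {pitch:.4f})"
            )
        slice_spacing = float(pitch)
    else:
        slice_spacing = float(getattr(slices[0], "SliceThickness", 1.0))
    row_sp, col_sp = (float(x) for x in slices[0].PixelSpacing)
    data = np.stack([s.pixel_array for s in slices]).astype(np.float32)
    origin = (positions[0], 0.0, 0.0)
    return VoxelVolume(data, (slice_spacing, row_sp, col_sp), origin)


# ---------------------------------------------------------------------------
# Resampling / resizing
# ---------------------------------------------------------------------------

_INTERP_ORDER = {"trilinear": 1, "nearest": 0}


def _resize_array(data: np.ndarray, out_shape: tuple[int, int, int], order: int) -> np.ndarray:
    """Resize a 3D array to an exact target shape (pixel-area grid alignment)."""
    in_shape = data.shape
    if tuple(out_shape) == tuple(in_shape):
        return data.copy()
    was_bool = data.dtype == bool
    work = data.astype(np.float32) if was_bool else data
    factors = [o / i for o, i in zip(out_shape, in_shape)]
    out = ndimage.zoom(work, factors, order=order, mode="nearest", grid_mode=True)
    assert out.shape == tuple(out_shape), (out.shape, out_shape)
    if was_bool:
        out = out > 0.5
    return out


def resample_isotropic(volume, target_spacing: float, interpolation: str = "trilinear"):
    """Resample to isotropic voxels of edge ``target_spacing`` mm.

    Output extents are ``round(extent * spacing / target)`` per axis (min 1),
    so the physical extent is preserved to within one voxel per axis.  Masks
    must use ``interpolation='nearest'``; :class:`BinaryMask` inputs are
    forced to nearest regardless.
    """
    if not target_spacing > 0:
        raise ValueError(f"target_spacing must be > 0, got {target_spacing}")
    if interpolation not in _INTERP_ORDER:
        raise ValueError(f"unknown interpolation {interpolation!r}")
    is_mask = isinstance(volume, BinaryMask)
    order = 0 if is_mask else _INTERP_ORDER[interpolation]
    target_spacing = float(np.float32(target_spacing))
    out_shape = tuple(
        max(1, int(round(n * s / target_spacing)))
        for n, s in zip(volume.shape, volume.spacing)
    )
    out = _resize_array(volume.data, out_shape, order)
    spacing = (target_spacing,) * 3
    cls = BinaryMask if is_mask else VoxelVolume
    return cls(out, spacing, volume.origin)


@dataclass
class ScaleRecord:
    """Invertible record of a shape change made by :func:`resize_to_shape`.

    ``mode='interpolate'`` stores the per-axis zoom factors implicitly via the
    input/output shapes; ``mode='pad_crop'`` stores the centred pad widths and
    crop offsets applied per axis.
    """

    mode: str
    in_shape: tuple[int, int, int]
    out_shape: tuple[int, int, int]
    pad_before: tuple[int, int, int] = (0, 0, 0)
    crop_before: tuple[int, int, int] = (0, 0, 0)

    @property
    def factors(self) -> tuple[float, float, float]:
        return tuple(o / i for o, i in zip(self.out_shape, self.in_shape))

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "in_shape": list(self.in_shape),
            "out_shape": list(self.out_shape),
            "pad_before": list(self.pad_before),
            "crop_before": list(self.crop_before),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScaleRecord":
        return cls(
            mode=d["mode"],
            in_shape=tuple(d["in_shape"]),
            out_shape=tuple(d["out_shape"]),
            pad_before=tuple(d.get("pad_before", (0, 0, 0))),
            crop_before=tuple(d.get("crop_before", (0, 0, 0))),
        )


def resize_to_shape(volume, target_shape, mode: str = "interpolate"):
    """Resize to an exact target shape, returning the result and a ScaleRecord.

    ``interpolate`` rescales each axis (trilinear for intensities, nearest for
    masks) and adjusts spacing so the physical extent is preserved;
    ``pad_crop`` centre-pads with zeros / centre-crops and keeps spacing.
    """
    target_shape = tuple(int(t) for t in target_shape)
    if len(target_shape) != 3 or min(target_shape) < 1:
        raise ValueError(f"target_shape must be 3 positive ints, got {target_shape}")
    if mode not in ("interpolate", "pad_crop"):
        raise ValueError(f"unknown resize mode {mode!r}")
    is_mask = isinstance(volume, BinaryMask)
    in_shape = volume.shape
    if mode == "interpolate":
        order = 0 if is_mask else 1
        out = _resize_array(volume.data, target_shape, order)
        spacing = tuple(
            s * i / o for s, i, o in zip(volume.spacing, in_shape, target_shape)
        )
        record = ScaleRecord("interpolate", in_shape, target_shape)
    else:
        pad_before, crop_before = [], []
        out = volume.data
        pads, crops = [], []
        for ax, (n, t) in enumerate(zip(in_shape, target_shape)):
            diff = t - n
            if diff >= 0:
                pads.append((diff // 2, diff - diff // 2))
                crops.append((0, n))
                pad_before.append(diff // 2)
                crop_before.append(0)
            else:
                start = (-diff) // 2
                pads.append((0, 0))
                crops.append((start, start + t))
                pad_before.append(0)
                crop_before.append(start)
        out = out[crops[0][0]:crops[0][1], crops[1][0]:crops[1][1], crops[2][0]:crops[2][1]]
        out = np.pad(out, pads)
        spacing = volume.spacing
        record = ScaleRecord("pad_crop", in_shape, target_shape,
                             tuple(pad_before), tuple(crop_before))
    cls = BinaryMask if is_mask else VoxelVolume
    return cls(out, spacing, volume.origin), record


def invert_resize(data: np.ndarray, record: ScaleRecord, order: int = 1) -> np.ndarray:
    """Invert the shape change recorded by :func:`resize_to_shape`.

    Exactly inverts the shape (content is re-interpolated for the
    ``interpolate`` mode; cropped-away regions come back as zeros for
    ``pad_crop``).
    """
    if tuple(data.shape) != tuple(record.out_shape):
        raise ValueError(
            f"data shape {data.shape} does not match record out_shape {record.out_shape}"
        )
    if record.mode == "interpolate":
        return _resize_array(data, record.in_shape, 0 if data.dtype == bool else order)
    out = np.zeros(record.in_shape, dtype=data.dtype)
    src_slices, dst_slices = [], []
    for ax in range(3):
        n, t = record.in_shape[ax], record.out_shape[ax]
        pb, cb = record.pad_before[ax], record.crop_before[ax]
        if t >= n:  # axis was padded; strip the padding
            src_slices.append(slice(pb, pb + n))
            dst_slices.append(slice(0, n))
        else:  # axis was cropped; re-embed at the recorded offset
            src_slices.append(slice(0, t))
            dst_slices.append(slice(cb, cb + t))
    out[tuple(dst_slices)] = data[tuple(src_slices)]
    return out


def load_labelmap_masks(labelmap_path: str, sidecar_json_path: str) -> dict[int, BinaryMask]:
    """Load per-tooth masks from an integer labelmap + FDI sidecar JSON.

    The sidecar maps FDI codes to integer label values, e.g.
    ``{"36": 1, "37": 2}``; returns one BinaryMask per tooth.
    """
    import json

    volume = read_volume(labelmap_path)
    with open(sidecar_json_path) as fh:
        mapping = json.load(fh)
    labels = np.rint(volume.data).astype(int)
    masks = {}
    for fdi, value in mapping.items():
        fdi = int(fdi)
        if fdi not in _FDI:
            raise ValueError(f"sidecar names invalid FDI code {fdi}")
        masks[fdi] = BinaryMask(labels == int(value), volume.spacing, volume.origin)
    return masks


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap of two boolean arrays; 1.0 for two empty masks."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.logical_and(a, b).sum() / denom
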