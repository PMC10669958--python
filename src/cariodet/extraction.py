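"""Per-tooth crop / normalize / restore geometry.

A tooth sub-volume is prepared for the network in three steps, recorded in a
:class:`CropTransform` so predictions can be mapped back to the source scan:

1. crop to the tooth-mask bounding box expanded by a physical margin
   (default 3 mm per side),
2. resample the crop to isotropic voxels (default 0.25 mm), and
3. resize to the fixed network input shape (default 96 x 64 x 64).

Intensities use trilinear interpolation throughout; masks use nearest
neighbour.  Expanded boxes are clipped at the scan border rather than padded,
which avoids inventing intensities.  For disconnected (e.g. multi-rooted)
masks the box covers the union of all components.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError
from .geometry import (
    BinaryMask,
    ScaleRecord,
    VoxelVolume,
    ToothEntry,
    invert_resize,
    resample_isotropic,
    resize_to_shape,
    _resize_array,
)

__all__ = [
    "PipelineConfig",
    "CropTransform",
    "tooth_bounding_box",
    "extract_tooth_volume",
    "restore_to_original",
]


@dataclass
class PipelineConfig:
    """Tunable geometry and post-processing parameters of the tooth pipeline.

    margin_mm
        Physical margin added on each side of the tooth bounding box.
    target_spacing_mm
        Isotropic voxel edge the crop is resampled to before the network.
    input_shape
        Fixed network input shape (tooth long axis first).
    min_lesion_volume_cm3
        Lesion components strictly smaller than this are discarded.
    dilation_radius_voxels
        Radius of the binary dilation applied to the tooth mask before
        intersecting it with the predicted lesion mask.
    resize_mode
        How the fixed input shape is reached: 'interpolate' or 'pad_crop'.
    """

    margin_mm: float = 3.0
    target_spacing_mm: float = 0.25
    input_shape: tuple[int, int, int] = (96, 64, 64)
    min_lesion_volume_cm3: float = 0.3
    dilation_radius_voxels: int = 1
    resize_mode: str = "interpolate"

    def __post_init__(self):
        self.input_shape = tuple(int(x) for x in self.input_shape)
        if len(self.input_shape) != 3 or min(self.input_shape) < 1:
            raise ValueError(f"input_shape must be 3 positive ints, got {self.input_shape}")
        for name in ("margin_mm", "target_spacing_mm", "min_lesion_volume_cm3"):
            if not getattr(self, name) >= 0 or (
                name != "margin_mm" and not getattr(self, name) > 0
            ):
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if self.dilation_radius_voxels < 0:
            raise ValueError("dilation_radius_voxels must be >= 0")
        if self.resize_mode not in ("interpolate", "pad_crop"):
            raise ValueError(f"unknown resize_mode {self.resize_mode!r}")

    def to_dict(self) -> dict:
        return {
            "margin_mm": self.margin_mm,
            "target_spacing_mm": self.target_spacing_mm,
            "input_shape": list(self.input_shape),
            "min_lesion_volume_cm3": self.min_lesion_volume_cm3,
            "dilation_radius_voxels": self.dilation_radius_voxels,
            "resize_mode": self.resize_mode,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)


@dataclass
class CropTransform:
    """Invertible record of the crop -> resample -> resize chain."""

    bbox: tuple[tuple[int, int], tuple[int, int], tuple[int, int]]
    source_shape: tuple[int, int, int]
    source_spacing: tuple[float, float, float]
    intermediate_spacing: float
    intermediate_shape: tuple[int, int, int]
    scale_record: ScaleRecord

    def __post_init__(self):
        for (lo, hi), n in zip(self.bbox, self.source_shape):
            if not (0 <= lo < hi <= n):
                raise ValueError(f"bbox {self.bbox} not within source shape {self.source_shape}")

    @property
    def bbox_shape(self) -> tuple[int, int, int]:
        return tuple(hi - lo for lo, hi in self.bbox)

    def to_json(self) -> str:
        return json.dumps(
            {
                "bbox": [list(iv) for iv in self.bbox],
                "source_shape": list(self.source_shape),
                "source_spacing": list(self.source_spacing),
                "intermediate_spacing": self.intermediate_spacing,
                "intermediate_shape": list(self.intermediate_shape),
                "scale_record": self.scale_record.to_dict(),
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, s: str) -> "CropTransform":
        d = json.loads(s)
        return cls(
            bbox=tuple(tuple(iv) for iv in d["bbox"]),
            source_shape=tuple(d["source_shape"]),
            source_spacing=tuple(d["source_spacing"]),
            intermediate_spacing=d["intermediate_spacing"],
            intermediate_shape=tuple(d["intermediate_shape"]),
            scale_record=ScaleRecord.from_dict(d["scale_record"]),
        )


def tooth_bounding_box(mask: BinaryMask, margin_mm: float = 3.0):
    """Tight bounding box of the mask, expanded by a physical margin.

    The margin is converted to ``round(margin_mm / spacing)`` voxels per axis
    and the expanded half-open intervals are clipped to the volume extents.
    """
    data = mask.data
    if not data.any():
        raise DomainError("no tooth voxels: cannot compute a bounding box of an empty mask")
    bbox = []
    for ax in range(3):
        other = tuple(i for i in range(3) if i != ax)
        profile = data.any(axis=other)
        idx = np.nonzero(profile)[0]
        lo, hi = int(idx[0]), int(idx[-1]) + 1
        m = int(round(margin_mm / mask.spacing[ax]))
        bbox.append((max(0, lo - m), min(data.shape[ax], hi + m)))
    return tuple(bbox)


def extract_tooth_volume(volume: VoxelVolume, tooth: ToothEntry, config: PipelineConfig):
    """Crop, resample and resize one tooth for the network.

    Returns ``(tooth_volume, tooth_mask, transform)`` where both outputs have
    shape ``config.input_shape`` and the :class:`CropTransform` suffices to
    map network-space predictions back onto the source scan.
    """
    mask = tooth.mask
    if not mask.matches_geometry(volume):
        raise ValueError(
            f"mask geometry {mask.shape}/{mask.spacing} does not match "
            f"volume {volume.shape}/{volume.spacing}"
        )
    bbox = tooth_bounding_box(mask, config.margin_mm)
    sl = tuple(slice(lo, hi) for lo, hi in bbox)
    crop_vol = VoxelVolume(volume.data[sl], volume.spacing, volume.origin)
    crop_mask = BinaryMask(mask.data[sl], mask.spacing, mask.origin)

    iso_vol = resample_isotropic(crop_vol, config.target_spacing_mm, "trilinear")
    iso_mask = resample_isotropic(crop_mask, config.target_spacing_mm, "nearest")

    out_vol, record = resize_to_shape(iso_vol, config.input_shape, config.resize_mode)
    out_mask, _ = resize_to_shape(iso_mask, config.input_shape, config.resize_mode)

    transform = CropTransform(
        bbox=bbox,
        source_shape=volume.shape,
        source_spacing=volume.spacing,
        intermediate_spacing=float(np.float32(config.target_spacing_mm)),
        intermediate_shape=iso_vol.shape,
        scale_record=record,
    )
    return out_vol, out_mask, transform


def transform_mask(mask: BinaryMask, transform: CropTransform) -> BinaryMask:
    """Carry an auxiliary full-volume mask through a recorded crop chain.

    Applies the same crop / isotropic resample / resize as the extraction
    that produced ``transform``, with nearest-neighbour interpolation; used
    e.g. to bring a ground-truth lesion mask into network space.
    """
    if tuple(mask.shape) != tuple(transform.source_shape):
        raise ValueError(
            f"mask shape {mask.shape} does not match transform source "
            f"{transform.source_shape}"
        )
    sl = tuple(slice(lo, hi) for lo, hi in transform.bbox)
    crop = BinaryMask(mask.data[sl], mask.spacing, mask.origin)
    iso = resample_isotropic(crop, transform.intermediate_spacing, "nearest")
    out, _ = resize_to_shape(iso, transform.scale_record.out_shape,
                             transform.scale_record.mode)
    return out


def restore_to_original(prediction: np.ndarray, transform: CropTransform) -> np.ndarray:
    """Map a network-space prediction back to the original volume geometry.

    Boolean predictions are restored with nearest-neighbour interpolation,
    scalar ones with trilinear.  Voxels outside the crop box are zero/False.
    """
    prediction = np.asarray(prediction)
    if tuple(prediction.shape) != tuple(transform.scale_record.out_shape):
        raise ValueError(
            f"prediction shape {prediction.shape} does not match network shape "
            f"{transform.scale_record.out_shape}"
        )
    is_bool = prediction.dtype == bool
    order = 0 if is_bool else 1
    # undo the fixed-shape resize, then the isotropic resample
    mid = invert_resize(prediction, transform.scale_record, order=order)
    box = _resize_array(mid, transform.bbox_shape, order)
    out = np.zeros(transform.source_shape, dtype=prediction.dtype)
    sl = tuple(slice(lo, hi) for lo, hi in transform.bbox)
    out[sl] = box
    return out
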