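"""Lesion post-processing: components, volume filter, calibration, tooth gating.

Raw network output becomes a final per-tooth lesion call in four steps:

1. the voxelwise probability grid is recalibrated (see below) and
   thresholded into a binary candidate mask,
2. the candidate mask is restricted to the tooth of interest by intersecting
   it with a binary dilation of the tooth mask, removing predictions inside
   neighbouring teeth,
3. the surviving voxels are labeled into connected components
   (26-connectivity by default), and
4. components with a physical volume strictly below the threshold
   (0.3 cm^3 by default) are discarded.

Restricting to the tooth *before* component labeling (rather than last)
guarantees two properties at once: every surviving component meets the
volume threshold and the whole pipeline is idempotent.

Probability recalibration anchors the Youden-optimal operating threshold t*
(the maximizer of sensitivity + specificity) at probability 0.5 with the
minimal monotone piecewise-linear map fixing 0 -> 0, t* -> 0.5 and 1 -> 1.

Note on the volume threshold: the 0.3 cm^3 (= 300 mm^3) default is very
large relative to a whole tooth (~1 cm^3); it is kept as the default but is
fully configurable (``PipelineConfig.min_lesion_volume_cm3``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure

from .errors import DomainError
from .extraction import PipelineConfig
from .geometry import BinaryMask
from .network import CariesPrediction

__all__ = [
    "LesionComponent",
    "CalibrationMap",
    "label_components",
    "filter_by_volume",
    "calibrate_threshold",
    "rescale_probability",
    "intersect_with_tooth",
    "run_postprocess",
]

_CONNECTIVITY_ORDER = {6: 1, 18: 2, 26: 3}


@dataclass
class LesionComponent:
    """One connected predicted lesion."""

    component_id: int
    voxel_count: int
    volume_mm3: float
    bbox: tuple[tuple[int, int], tuple[int, int], tuple[int, int]]

    def to_dict(self) -> dict:
        return {
            "component_id": self.component_id,
            "voxel_count": self.voxel_count,
            "volume_mm3": self.volume_mm3,
            "bbox": [list(iv) for iv in self.bbox],
        }


@dataclass
class CalibrationMap:
    """The Youden-anchored threshold mapped to probability 0.5."""

    t_star: float

    def __post_init__(self):
        if not 0.0 < self.t_star < 1.0:
            raise ValueError(f"t_star must be in (0, 1), got {self.t_star}")

    def to_json(self) -> str:
        return json.dumps({"t_star": self.t_star})

    @classmethod
    def from_json(cls, s: str) -> "CalibrationMap":
        return cls(**json.loads(s))


def label_components(mask: BinaryMask | np.ndarray, connectivity: int = 26,
                     spacing=None):
    """Label maximal connected sets of true voxels.

    Returns ``(components, labeled_grid)`` with labels dense from 1.
    ``connectivity`` is 6 (faces), 18 (+edges) or 26 (+corners).
    """
    if connectivity not in _CONNECTIVITY_ORDER:
        raise ValueError(f"connectivity must be one of {sorted(_CONNECTIVITY_ORDER)}")
    if isinstance(mask, BinaryMask):
        data, spacing = mask.data, mask.spacing
    else:
        data = np.asarray(mask, bool)
        spacing = (1.0, 1.0, 1.0) if spacing is None else tuple(spacing)
    labeled = measure.label(data, connectivity=_CONNECTIVITY_ORDER[connectivity])
    vox_mm3 = float(np.prod(spacing))
    components = []
    for region in measure.regionprops(labeled):
        lo = tuple(int(b) for b in region.bbox[:3])
        hi = tuple(int(b) for b in region.bbox[3:])
        components.append(LesionComponent(
            component_id=int(region.label),
            voxel_count=int(region.area),
            volume_mm3=float(region.area) * vox_mm3,
            bbox=tuple(zip(lo, hi)),
        ))
    return components, labeled


def filter_by_volume(components, spacing, min_volume_cm3: float):
    """Keep components whose physical volume is >= the threshold.

    Removal is strict-less ("lesions with a volume less than the threshold
    were ignored"): a component of exactly the threshold volume is retained.
    """
    spacing = tuple(float(s) for s in spacing)
    if any(s <= 0 for s in spacing):
        raise ValueError(f"spacing must be positive, got {spacing}")
    threshold_mm3 = float(min_volume_cm3) * 1000.0
    return [c for c in components if not c.volume_mm3 < threshold_mm3]


def calibrate_threshold(pred_probs, labels) -> CalibrationMap:
    """Find the tooth-probability threshold maximizing sensitivity + specificity.

    Candidates are the midpoints between adjacent distinct sorted
    probabilities; ties are broken toward the lower threshold.  A prediction
    is called positive when its probability is >= the threshold.
    """
    p = np.asarray(pred_probs, float)
    y = np.asarray(labels).astype(bool)
    if p.shape != y.shape or p.ndim != 1:
        raise ValueError("pred_probs and labels must be 1D of equal length")
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise DomainError("calibration requires both classes in the labels")
    distinct = np.unique(p)
    if distinct.size < 2:
        raise DomainError("calibration requires at least two distinct probabilities")
    candidates = (distinct[:-1] + distinct[1:]) / 2.0
    best_t, best_j = None, -np.inf
    for t in candidates:  # ascending, so strict '>' keeps the lowest maximizer
        called = p >= t
        sens = (called & y).sum() / n_pos
        spec = (~called & ~y).sum() / n_neg
        j = sens + spec
        if j > best_j:
            best_j, best_t = j, float(t)
    return CalibrationMap(t_star=min(max(best_t, 1e-9), 1 - 1e-9))


def rescale_probability(p, cal: CalibrationMap):
    """Piecewise-linear recalibration fixing 0 -> 0, t* -> 0.5, 1 -> 1.

    Strictly increasing and bijective on [0, 1]; accepts scalars or arrays.
    """
    arr = np.asarray(p, float)
    if arr.min() < 0.0 or arr.max() > 1.0:
        raise ValueError("probabilities must lie in [0, 1]")
    t = cal.t_star
    out = np.where(arr <= t, 0.5 * arr / t, 0.5 + 0.5 * (arr - t) / (1.0 - t))
    return float(out) if np.isscalar(p) or arr.ndim == 0 else out


def _dilation_structure(connectivity: int):
    return ndimage.generate_binary_structure(3, _CONNECTIVITY_ORDER[connectivity])


def intersect_with_tooth(lesion_mask: BinaryMask, tooth_mask: BinaryMask,
                         dilation_radius_voxels: int = 1,
                         connectivity: int = 26) -> BinaryMask:
    """Restrict predicted lesions to the (dilated) tooth of interest.

    The tooth mask is dilated ``radius`` times with the structuring element
    of the chosen connectivity and multiplied with the lesion mask, removing
    lesion predictions situated inside neighbouring teeth.
    """
    if not lesion_mask.matches_geometry(tooth_mask):
        raise ValueError("lesion and tooth mask geometries do not match")
    tooth = tooth_mask.data
    if dilation_radius_voxels > 0 and tooth.any():
        tooth = ndimage.binary_dilation(
            tooth, structure=_dilation_structure(connectivity),
            iterations=dilation_radius_voxels,
        )
    return lesion_mask.with_data(lesion_mask.data & tooth)


def run_postprocess(pred: CariesPrediction, tooth_mask: BinaryMask,
                    config: PipelineConfig, cal: CalibrationMap,
                    prob_cutoff: float = 0.5, connectivity: int = 26):
    """Full post-processing of one tooth prediction.

    Returns ``(final_mask, components, rescaled_tooth_prob)``.  The voxel
    cutoff applies on the recalibrated probability scale, so the default 0.5
    corresponds to the Youden operating point of the raw network output.
    """
    lesion_prob = np.asarray(pred.lesion_prob)
    if lesion_prob.shape != tooth_mask.shape:
        raise ValueError(
            f"prediction shape {lesion_prob.shape} does not match tooth mask "
            f"{tooth_mask.shape}"
        )
    binary = rescale_probability(lesion_prob, cal) >= prob_cutoff
    candidate = tooth_mask.with_data(binary)
    gated = intersect_with_tooth(candidate, tooth_mask,
                                 config.dilation_radius_voxels, connectivity)
    components, labeled = label_components(gated, connectivity)
    kept = filter_by_volume(components, tooth_mask.spacing,
                            config.min_lesion_volume_cm3)
    keep_ids = {c.component_id for c in kept}
    final = np.isin(labeled, sorted(keep_ids)) if keep_ids else np.zeros_like(binary)
    rescaled_tooth_prob = rescale_probability(float(pred.tooth_prob), cal)
    return tooth_mask.with_data(final), kept, rescaled_tooth_prob
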