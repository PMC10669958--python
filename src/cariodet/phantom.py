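"""Procedural tooth phantoms and synthetic reader-rating tables.

Every other module is testable without any download: this module generates
single-jaw-segment volumes containing a row of teeth (fused superellipsoid
crown + tapered root), low-intensity approximal lesions of controlled
physical volume placed on the mesial or distal crown surface, neighbouring
tooth clutter, and additive Gaussian noise.  It also simulates five-point
confidence ratings from observers of stated sensitivity/specificity.

Axis convention: axis 0 is the tooth long axis; teeth are placed in a row
along axis 2.  "Mesial" is the surface facing the neighbour at smaller
axis-2 coordinate, "distal" the one at larger axis-2 coordinate (a fixed
convention of the phantom, not an anatomical statement).

Everything is deterministic given the spec seed; the geometry, noise and
rating streams are split so each is independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .geometry import BinaryMask, VoxelVolume

__all__ = [
    "LesionSpec",
    "IntensityLevels",
    "PhantomSpec",
    "ObserverModel",
    "Phantom",
    "generate_phantom",
    "generate_dataset",
    "make_training_sample",
    "simulate_rating_study",
    "SURFACES",
]

SURFACES = ("mesial", "distal")


@dataclass(frozen=True)
class LesionSpec:
    tooth_id: int
    surface: str
    target_volume_mm3: float

    def __post_init__(self):
        if self.surface not in SURFACES:
            raise ValueError(f"surface must be one of {SURFACES}, got {self.surface!r}")
        if not self.target_volume_mm3 > 0:
            raise ValueError("lesion target volume must be > 0")


@dataclass(frozen=True)
class IntensityLevels:
    """Relative grey levels (arbitrary CBCT-like units in [0, 1])."""

    background: float = 0.05
    dentin: float = 0.55
    enamel: float = 0.95
    lesion_contrast: float = 0.6  # lesion intensity = dentin * (1 - contrast)

    @property
    def lesion(self) -> float:
        return self.dentin * (1.0 - self.lesion_contrast)


@dataclass(frozen=True)
class PhantomSpec:
    """Full specification of one procedural phantom."""

    grid_shape: tuple[int, int, int] = (96, 64, 64)
    spacing_mm: float = 0.25
    n_teeth: int = 3
    crown_semi_axes_mm: tuple[float, float, float] = (3.2, 2.2, 2.2)
    crown_exponent: float = 2.5
    root_length_mm: float = 8.0
    root_taper: float = 0.7
    enamel_thickness_mm: float = 0.5
    intensities: IntensityLevels = field(default_factory=IntensityLevels)
    lesions: tuple[LesionSpec, ...] = ()
    noise_sigma: float = 0.02
    streak_artifacts: bool = False
    seed: int = 0
    case_id: str = "phantom"

    def __post_init__(self):
        object.__setattr__(self, "grid_shape", tuple(int(x) for x in self.grid_shape))
        object.__setattr__(self, "lesions",
                           tuple(l if isinstance(l, LesionSpec) else LesionSpec(*l)
                                 for l in self.lesions))
        if self.n_teeth < 1:
            raise ValueError("n_teeth must be >= 1")
        if not self.spacing_mm > 0:
            raise ValueError("spacing_mm must be > 0")
        ids = set(self.tooth_ids())
        for les in self.lesions:
            if les.tooth_id not in ids:
                raise ValueError(f"lesion names unknown tooth {les.tooth_id}; phantom has {sorted(ids)}")

    def tooth_ids(self) -> list[int]:
        """FDI codes assigned left-to-right along axis 2 (lower-left quadrant)."""
        return [31 + i for i in range(self.n_teeth)]


@dataclass
class Phantom:
    """A generated phantom: volume, per-tooth masks, per-lesion masks, truth."""

    volume: VoxelVolume
    tooth_masks: dict[int, BinaryMask]
    lesion_masks: dict[tuple[int, str], BinaryMask]
    surface_truth: pd.DataFrame
    spec: PhantomSpec

    def lesion_union(self, tooth_id: int) -> np.ndarray:
        """Union of the lesion masks belonging to one tooth."""
        out = np.zeros(self.volume.shape, bool)
        for (tid, _), m in self.lesion_masks.items():
            if tid == tooth_id:
                out |= m.data
        return out


def _tooth_mask_mm(zz, yy, xx, center, spec: PhantomSpec) -> np.ndarray:
    zc, yc, xc = center
    a, b, c = spec.crown_semi_axes_mm
    e = spec.crown_exponent
    crown = (np.abs((zz - zc) / a) ** e + np.abs((yy - yc) / b) ** e
             + np.abs((xx - xc) / c) ** e) <= 1.0
    # tapered root below the crown centre
    depth = zc - zz
    with np.errstate(divide="ignore", invalid="ignore"):
        t = 1.0 - spec.root_taper * depth / spec.root_length_mm
    in_z = (depth >= 0) & (depth <= spec.root_length_mm)
    rb, rc = 0.75 * b, 0.75 * c
    root = in_z & (((yy - yc) / (rb * np.maximum(t, 1e-6))) ** 2
                   + ((xx - xc) / (rc * np.maximum(t, 1e-6))) ** 2 <= 1.0)
    return crown | root


def _erode_mm(mask: np.ndarray, spacing: float, thickness_mm: float) -> np.ndarray:
    from scipy import ndimage
    it = max(1, int(round(thickness_mm / spacing)))
    return ndimage.binary_erosion(mask, iterations=it)


def _lesion_mask(zz, yy, xx, surface_point, radius_mm, tooth: np.ndarray) -> np.ndarray:
    zc, yc, xc = surface_point
    ball = ((zz - zc) ** 2 + (yy - yc) ** 2 + (xx - xc) ** 2) <= radius_mm ** 2
    return ball & tooth


def generate_phantom(spec: PhantomSpec) -> Phantom:
    """Generate a phantom; deterministic given ``spec.seed``.

    Each lesion is grown (bisection on the cap radius) until its realized
    voxel volume is within 10% of the requested target; a target volume that
    cannot fit in the tooth raises ``ValueError``.
    """
    shape = spec.grid_shape
    sp = spec.spacing_mm
    ss = np.random.SeedSequence(spec.seed)
    noise_rng, streak_rng = (np.random.default_rng(s) for s in ss.spawn(2))

    coords = [(np.arange(n) + 0.5) * sp for n in shape]
    zz, yy, xx = np.meshgrid(*coords, indexing="ij", sparse=True)

    extent = [n * sp for n in shape]
    z_crown = 0.62 * extent[0]
    yc = 0.5 * extent[1]
    pitch = extent[2] / spec.n_teeth
    centers = {
        tid: (z_crown, yc, (i + 0.5) * pitch)
        for i, tid in enumerate(spec.tooth_ids())
    }

    tooth_masks: dict[int, np.ndarray] = {}
    for tid, center in centers.items():
        tooth_masks[tid] = _tooth_mask_mm(zz, yy, xx, center, spec)

    lesion_masks: dict[tuple[int, str], np.ndarray] = {}
    vox_mm3 = sp ** 3
    for les in spec.lesions:
        tooth = tooth_masks[les.tooth_id]
        tooth_vol = tooth.sum() * vox_mm3
        if les.target_volume_mm3 > tooth_vol:
            raise ValueError(
                f"lesion target volume {les.target_volume_mm3} mm^3 exceeds tooth "
                f"{les.tooth_id} volume {tooth_vol:.1f} mm^3"
            )
        zc, ycen, xc = centers[les.tooth_id]
        c = spec.crown_semi_axes_mm[2]
        x_surface = xc - c if les.surface == "mesial" else xc + c
        point = (zc, ycen, x_surface)
        target_vox = les.target_volume_mm3 / vox_mm3

        lo, hi = 0.1, max(extent)
        mask = None
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            mask = _lesion_mask(zz, yy, xx, point, mid, tooth)
            count = mask.sum()
            if abs(count - target_vox) / target_vox <= 0.02:
                break
            if count < target_vox:
                lo = mid
            else:
                hi = mid
        realized = mask.sum() * vox_mm3
        if abs(realized - les.target_volume_mm3) / les.target_volume_mm3 > 0.10:
            raise ValueError(
                f"could not realize lesion volume {les.target_volume_mm3} mm^3 on "
                f"tooth {les.tooth_id} (best: {realized:.1f} mm^3)"
            )
        lesion_masks[(les.tooth_id, les.surface)] = mask

    # compose intensities
    data = np.full(shape, spec.intensities.background, np.float32)
    all_teeth = np.zeros(shape, bool)
    for tid, mask in tooth_masks.items():
        all_teeth |= mask
    data[all_teeth] = spec.intensities.dentin
    for tid, center in centers.items():
        crown = (np.abs((zz - center[0]) / spec.crown_semi_axes_mm[0]) ** spec.crown_exponent
                 + np.abs((yy - center[1]) / spec.crown_semi_axes_mm[1]) ** spec.crown_exponent
                 + np.abs((xx - center[2]) / spec.crown_semi_axes_mm[2]) ** spec.crown_exponent) <= 1.0
        shell = crown & ~_erode_mm(crown, sp, spec.enamel_thickness_mm)
        data[shell] = spec.intensities.enamel
    for mask in lesion_masks.values():
        data[mask] = spec.intensities.lesion

    if spec.streak_artifacts:
        for _ in range(3):
            axis = int(streak_rng.integers(3))
            idx = [slice(None)] * 3
            for ax in range(3):
                if ax != axis:
                    idx[ax] = int(streak_rng.integers(shape[ax]))
            data[tuple(idx)] += 0.3
    if spec.noise_sigma > 0:
        data = data + noise_rng.normal(0.0, spec.noise_sigma, shape).astype(np.float32)

    spacing = (sp, sp, sp)
    volume = VoxelVolume(data, spacing)
    truth_rows = []
    for tid in spec.tooth_ids():
        for surface in SURFACES:
            key = (tid, surface)
            carious = key in lesion_masks
            truth_rows.append({
                "case_id": spec.case_id,
                "tooth_fdi": tid,
                "surface": surface,
                "carious": carious,
                "lesion_volume_mm3": (lesion_masks[key].sum() * vox_mm3) if carious else 0.0,
            })
    return Phantom(
        volume=volume,
        tooth_masks={t: BinaryMask(m, spacing) for t, m in tooth_masks.items()},
        lesion_masks={k: BinaryMask(m, spacing) for k, m in lesion_masks.items()},
        surface_truth=pd.DataFrame(truth_rows),
        spec=spec,
    )


def generate_dataset(base_spec: PhantomSpec, n_samples: int, master_seed: int,
                     prevalence: float = 0.5,
                     volume_range_mm3: tuple[float, float] = (10.0, 40.0)):
    """Reproducible fan-out of per-sample specs from one master seed.

    Carious samples (drawn with the given prevalence) carry one lesion on the
    middle tooth, on a random surface, with a target volume drawn uniformly
    from ``volume_range_mm3``.  Returns ``(specs, manifest)``.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    ss = np.random.SeedSequence(master_seed)
    child_seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(n_samples)]
    rng = np.random.default_rng(np.random.SeedSequence(master_seed).spawn(n_samples + 1)[-1])
    mid_tooth = base_spec.tooth_ids()[len(base_spec.tooth_ids()) // 2]
    specs, rows = [], []
    for i, seed in enumerate(child_seeds):
        carious = bool(rng.random() < prevalence)
        if carious:
            surface = SURFACES[int(rng.integers(2))]
            vol = float(rng.uniform(*volume_range_mm3))
            lesions = (LesionSpec(mid_tooth, surface, vol),)
        else:
            surface, vol, lesions = "", 0.0, ()
        spec = replace(base_spec, seed=seed, lesions=lesions,
                       case_id=f"sample{i:04d}")
        specs.append(spec)
        rows.append({"sample_id": spec.case_id, "seed": seed, "carious": carious,
                     "surface": surface, "target_volume_mm3": vol,
                     "tooth_fdi": mid_tooth if carious else -1})
    return specs, pd.DataFrame(rows)


def make_training_sample(spec: PhantomSpec, tooth_id: int | None = None):
    """Generate one (volume, lesion mask, label) triple at the phantom grid.

    Used to train at phantom scale without the crop/resample chain; the
    lesion mask is the union of the named tooth's lesions.
    """
    ph = generate_phantom(spec)
    if tooth_id is None:
        tooth_id = spec.tooth_ids()[len(spec.tooth_ids()) // 2]
    mask = ph.lesion_union(tooth_id)
    return ph.volume.data, mask, float(mask.any())


# ---------------------------------------------------------------------------
# Synthetic observers
# ---------------------------------------------------------------------------

def _default_score_dists():
    # binarization-consistent: a positive call only ever yields scores 4-5,
    # a negative call only scores 1-3
    return {
        (True, True): (0.0, 0.0, 0.0, 0.4, 0.6),
        (True, False): (0.2, 0.45, 0.35, 0.0, 0.0),
        (False, False): (0.5, 0.38, 0.12, 0.0, 0.0),
        (False, True): (0.0, 0.0, 0.0, 0.65, 0.35),
    }


@dataclass
class ObserverModel:
    """A synthetic observer with stated binary operating characteristics.

    The observer first makes a latent binary call (caries present/absent)
    with the given sensitivity/specificity against the truth, then draws a
    five-point confidence score from the distribution conditioned on
    (truth, call).
    """

    sensitivity: float = 0.85
    specificity: float = 0.95
    score_dists: dict = field(default_factory=_default_score_dists)
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.sensitivity < 1.0 and 0.0 < self.specificity < 1.0):
            raise ValueError("sensitivity and specificity must lie in (0, 1)")
        for key, dist in self.score_dists.items():
            if abs(sum(dist) - 1.0) > 1e-9 or len(dist) != 5:
                raise ValueError(f"score distribution for {key} must be 5 probs summing to 1")


def simulate_rating_study(surface_truth: pd.DataFrame,
                          observers_by_arm: dict[str, dict[str, ObserverModel]],
                          session: int = 1) -> pd.DataFrame:
    """Simulate one rating per observer x arm x surface.

    ``surface_truth`` needs columns case_id, tooth_fdi, surface, carious.
    Deterministic given the observer seeds: the rating stream of an observer
    depends only on its model (two observers with identical models and seeds
    produce identical ratings).
    """
    truth = surface_truth.reset_index(drop=True)
    carious = truth["carious"].to_numpy(bool)
    n = len(truth)
    frames = []
    for arm, observers in observers_by_arm.items():
        for obs_id, model in observers.items():
            rng = np.random.default_rng(model.seed)
            u = rng.random(n)
            call = np.where(carious, u < model.sensitivity, u >= model.specificity)
            scores = np.zeros(n, int)
            for key, dist in model.score_dists.items():
                sel = (carious == key[0]) & (call == key[1])
                if sel.any():
                    scores[sel] = rng.choice(5, size=int(sel.sum()), p=dist) + 1
            frames.append(pd.DataFrame({
                "case_id": truth["case_id"],
                "tooth_fdi": truth["tooth_fdi"].astype(int),
                "surface": truth["surface"],
                "condition": "intact",
                "observer_id": obs_id,
                "arm": arm,
                "score": scores,
                "session": session,
            }))
    return pd.concat(frames, ignore_index=True)
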