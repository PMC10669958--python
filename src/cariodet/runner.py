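"""End-to-end orchestration: config validation and the run-all pipeline.

A run config is a YAML file combining the phantom spec, the geometry
pipeline config, the network/training hyperparameters and the synthetic
observer panel.  :func:`run_end_to_end` chains
phantom generation -> tooth extraction -> training -> prediction ->
post-processing -> rating simulation -> reader statistics, writing per-stage
artifacts and a JSON manifest with seeds and output checksums; rerunning
with the same config reproduces the manifest checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os

import numpy as np
import pandas as pd
import yaml

from . import reader_stats
from .errors import CariodetError, ValidationError
from .extraction import PipelineConfig, extract_tooth_volume, restore_to_original, transform_mask
from .geometry import ToothEntry, write_volume
from .network import CariesUNet, NetworkConfig
from .phantom import (
    IntensityLevels,
    ObserverModel,
    PhantomSpec,
    generate_dataset,
    generate_phantom,
    simulate_rating_study,
)
from .postprocess import calibrate_threshold, run_postprocess
from .training import train, normalize_volume

log = logging.getLogger("cariodet")

__all__ = ["RunConfig", "validate_config", "run_end_to_end", "demo_config"]

_KNOWN_TOP_KEYS = {"seed", "log_level", "phantom", "pipeline", "network",
                   "training", "observers", "calibration"}


@dataclasses.dataclass
class RunConfig:
    seed: int
    phantom_spec: PhantomSpec
    n_samples: int
    prevalence: float
    volume_range_mm3: tuple[float, float]
    pipeline: PipelineConfig
    network: NetworkConfig
    n_steps: int
    batch_size: int
    lr: float
    observers: dict[str, dict[str, ObserverModel]]
    log_level: str = "INFO"


def demo_config() -> dict:
    """A small, CPU-friendly run config (tiny phantoms, short training)."""
    return {
        "seed": 17,
        "log_level": "INFO",
        "phantom": {
            "grid_shape": [32, 32, 32],
            "spacing_mm": 0.5,
            "n_teeth": 3,
            "noise_sigma": 0.02,
            "n_samples": 4,
            "prevalence": 0.5,
            "volume_range_mm3": [15.0, 40.0],
        },
        "pipeline": {
            "margin_mm": 2.0,
            "target_spacing_mm": 0.5,
            "input_shape": [32, 32, 32],
            "min_lesion_volume_cm3": 0.001,
            "dilation_radius_voxels": 1,
        },
        "network": {"n_levels": 3, "base_channels": 2},
        "training": {"n_steps": 50, "batch_size": 2, "lr": 1e-3},
        "observers": {
            "unaided": {
                "observer1": {"sensitivity": 0.75, "specificity": 0.95, "seed": 11},
                "observer2": {"sensitivity": 0.77, "specificity": 0.94, "seed": 12},
                "observer3": {"sensitivity": 0.76, "specificity": 0.73, "seed": 13},
            },
            "aided": {
                "observer1": {"sensitivity": 0.87, "specificity": 0.97, "seed": 21},
                "observer2": {"sensitivity": 0.87, "specificity": 0.97, "seed": 22},
                "observer3": {"sensitivity": 0.88, "specificity": 0.92, "seed": 23},
            },
        },
    }


def _build(raw: dict, errors: list[str], warnings_: list[str]) -> RunConfig | None:
    for key in raw:
        if key not in _KNOWN_TOP_KEYS:
            warnings_.append(f"unknown config key {key!r} ignored")
    seed = raw.get("seed", 0)
    if not isinstance(seed, int) or seed < 0:
        errors.append("seed must be a nonnegative integer")
        seed = 0

    ph = dict(raw.get("phantom", {}))
    n_samples = ph.pop("n_samples", 4)
    prevalence = ph.pop("prevalence", 0.5)
    volume_range = tuple(ph.pop("volume_range_mm3", (15.0, 40.0)))
    if not 0.0 <= prevalence <= 1.0:
        errors.append(f"phantom.prevalence must be in [0, 1], got {prevalence}")
        prevalence = 0.5
    if "intensities" in ph:
        ph["intensities"] = IntensityLevels(**ph["intensities"])
    known_ph = {f.name for f in dataclasses.fields(PhantomSpec)}
    for key in list(ph):
        if key not in known_ph:
            warnings_.append(f"unknown phantom key {key!r} ignored")
            ph.pop(key)
    try:
        spec = PhantomSpec(seed=seed, **{k: v for k, v in ph.items() if k != "seed"})
    except (TypeError, ValueError) as exc:
        errors.append(f"phantom: {exc}")
        spec = PhantomSpec(seed=seed)

    pl = dict(raw.get("pipeline", {}))
    known_pl = {f.name for f in dataclasses.fields(PipelineConfig)}
    for key in list(pl):
        if key not in known_pl:
            warnings_.append(f"unknown pipeline key {key!r} ignored")
            pl.pop(key)
    try:
        pipeline = PipelineConfig(**pl)
    except (TypeError, ValueError) as exc:
        errors.append(f"pipeline: {exc}")
        pipeline = PipelineConfig()

    nw = dict(raw.get("network", {}))
    nw.setdefault("seed", seed)
    try:
        network = NetworkConfig(**nw)
    except (TypeError, ValueError) as exc:
        errors.append(f"network: {exc}")
        network = NetworkConfig(seed=seed)

    tr = dict(raw.get("training", {}))
    n_steps = tr.get("n_steps", 100)
    batch_size = tr.get("batch_size", 2)
    lr = tr.get("lr", 1e-3)
    if not (isinstance(n_steps, int) and n_steps > 0):
        errors.append(f"training.n_steps must be a positive int, got {n_steps}")
        n_steps = 100
    if not (isinstance(batch_size, int) and batch_size > 0):
        errors.append(f"training.batch_size must be a positive int, got {batch_size}")
        batch_size = 2
    if not lr > 0:
        errors.append(f"training.lr must be > 0, got {lr}")
        lr = 1e-3

    observers = {}
    for arm, panel in raw.get("observers", demo_config()["observers"]).items():
        observers[arm] = {}
        for obs_id, params in panel.items():
            try:
                observers[arm][obs_id] = ObserverModel(**params)
            except (TypeError, ValueError) as exc:
                errors.append(f"observers.{arm}.{obs_id}: {exc}")

    if errors:
        return None
    return RunConfig(
        seed=seed, phantom_spec=spec, n_samples=n_samples,
        prevalence=prevalence, volume_range_mm3=volume_range,
        pipeline=pipeline, network=network, n_steps=n_steps,
        batch_size=batch_size, lr=lr, observers=observers,
        log_level=raw.get("log_level", "INFO"),
    )


def validate_config(path_or_dict):
    """Validate a run config; returns ``(config_or_None, errors, warnings)``.

    All schema violations are collected and reported at once; unknown keys
    produce warnings, not errors.
    """
    if isinstance(path_or_dict, dict):
        raw = path_or_dict
    else:
        if not os.path.exists(path_or_dict):
            return None, [f"config file not found: {path_or_dict}"], []
        with open(path_or_dict) as fh:
            raw = yaml.safe_load(fh) or {}
    errors: list[str] = []
    warnings_: list[str] = []
    config = _build(raw, errors, warnings_)
    return config, errors, warnings_


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_end_to_end(config: RunConfig, out_dir: str) -> dict:
    """Run the full pipeline; returns (and writes) the run manifest."""
    logging.basicConfig(level=config.log_level)
    os.makedirs(out_dir, exist_ok=True)
    manifest = {"seed": config.seed, "stages": {}}

    def finish_stage(name, outputs, **extra):
        entry = {"outputs": {os.path.relpath(p, out_dir): _sha256(p) for p in outputs}}
        entry.update(extra)
        manifest["stages"][name] = entry
        log.info("stage %s done (%d outputs)", name, len(outputs))

    stage = "phantom"
    try:
        specs, man = generate_dataset(config.phantom_spec, config.n_samples,
                                      config.seed, config.prevalence,
                                      config.volume_range_mm3)
        ph_dir = os.path.join(out_dir, "phantoms")
        os.makedirs(ph_dir, exist_ok=True)
        man_path = os.path.join(ph_dir, "manifest.csv")
        man.to_csv(man_path, index=False)
        phantoms = [generate_phantom(s) for s in specs]
        truth = pd.concat([p.surface_truth for p in phantoms],
                                            ignore_index=True)
        truth_path = os.path.join(ph_dir, "surface_truth.csv")
        truth.to_csv(truth_path, index=False)
        outputs = [man_path, truth_path]
        for spec, ph in zip(specs, phantoms):
            vol_path = os.path.join(ph_dir, f"{spec.case_id}_volume.nii")
            write_volume(ph.volume, vol_path)
            outputs.append(vol_path)
        finish_stage(stage, outputs, n_samples=len(specs))

        stage = "extraction"
        mid = config.phantom_spec.tooth_ids()[len(config.phantom_spec.tooth_ids()) // 2]
        pairs, transforms = [], []
        for ph in phantoms:
            tooth = ToothEntry(mid, ph.tooth_masks[mid])
            vol, _tm, tf = extract_tooth_volume(ph.volume, tooth, config.pipeline)
            lesion = transform_mask(
                ph.tooth_masks[mid].with_data(ph.lesion_union(mid)), tf)
            pairs.append((vol.data, lesion.data, float(lesion.data.any())))
            transforms.append(tf)
        ex_dir = os.path.join(out_dir, "extraction")
        os.makedirs(ex_dir, exist_ok=True)
        tf_path = os.path.join(ex_dir, "transforms.json")
        with open(tf_path, "w") as fh:
            json.dump([json.loads(t.to_json()) for t in transforms], fh)
        finish_stage(stage, [tf_path], tooth_fdi=mid)

        stage = "training"
        net = CariesUNet(config.network)
        history = train(net, pairs, n_steps=config.n_steps,
                        batch_size=config.batch_size, lr=config.lr,
                        seed=config.seed)
        ck_dir = os.path.join(out_dir, "checkpoint")
        os.makedirs(ck_dir, exist_ok=True)
        w_path = os.path.join(ck_dir, "weights.npz")
        c_path = os.path.join(ck_dir, "network.json")
        net.save(w_path, c_path)
        h_path = os.path.join(ck_dir, "loss_history.json")
        with open(h_path, "w") as fh:
            json.dump(history, fh)
        finish_stage(stage, [w_path, c_path, h_path],
                     initial_loss=history[0], final_loss=history[-1])

        stage = "postprocess"
        preds = [net.predict_volume(normalize_volume(v)) for v, _, _ in pairs]
        tooth_probs = np.array([p.tooth_prob for p in preds])
        labels = np.array([lab for _, _, lab in pairs], bool)
        if labels.any() and not labels.all():
            cal = calibrate_threshold(tooth_probs, labels)
        else:  # degenerate single-class demo runs: identity calibration
            from .postprocess import CalibrationMap
            cal = CalibrationMap(0.5)
        pp_dir = os.path.join(out_dir, "predictions")
        os.makedirs(pp_dir, exist_ok=True)
        outputs = []
        rows = []
        for i, (ph, pred, tf) in enumerate(zip(phantoms, preds, transforms)):
            tooth_mask_net = transform_mask(ph.tooth_masks[mid], tf)
            final, comps, prob = run_postprocess(pred, tooth_mask_net,
                                                 config.pipeline, cal)
            restored = restore_to_original(final.data, tf)
            path = os.path.join(pp_dir, f"{specs[i].case_id}_lesion.nii")
            write_volume(ph.tooth_masks[mid].with_data(restored), path)
            outputs.append(path)
            rows.append({"sample": specs[i].case_id,
                         "tooth_prob": prob, "n_components": len(comps)})
        cal_path = os.path.join(pp_dir, "calibration.json")
        with open(cal_path, "w") as fh:
            fh.write(cal.to_json())
        pred_path = os.path.join(pp_dir, "tooth_predictions.csv")
        pd.DataFrame(rows).to_csv(pred_path, index=False)
        finish_stage(stage, outputs + [cal_path, pred_path], t_star=cal.t_star)

        stage = "reader_stats"
        ratings = simulate_rating_study(truth, config.observers)
        gt, conflicts = reader_stats.consensus_ground_truth(ratings, "unaided")
        if len(conflicts):
            # adjudicate conflicts from the phantom truth (the simulated
            # senior-radiologist session has access to it)
            dec = truth.rename(columns={"carious": "label"})[
                ["case_id", "tooth_fdi", "surface", "label"]].copy()
            dec["label"] = np.where(dec["label"].astype(bool),
                                    reader_stats.PRESENCE, reader_stats.ABSENCE)
            gt = reader_stats.merge_adjudication(gt, conflicts, dec)
        report = reader_stats.full_report(ratings, gt)
        rep_dir = os.path.join(out_dir, "report")
        rep_path = reader_stats.save_report(report, rep_dir)
        ratings_path = os.path.join(rep_dir, "ratings.csv")
        ratings.to_csv(ratings_path, index=False)
        finish_stage(stage, [rep_path, ratings_path],
                     n_surfaces=int(len(gt)), n_conflicts=int(len(conflicts)))
    except CariodetError:
        raise
    except Exception as exc:
        raise CariodetError(f"stage {stage!r} failed: {exc}") from exc

    man_path = os.path.join(out_dir, "manifest.json")
    with open(man_path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
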