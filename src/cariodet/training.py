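"""Training loop and a scikit-learn-style estimator for the caries network.

The segmentation objective is the sum of a soft-Jaccard loss and voxel-mean
binary cross-entropy; the tooth-level classification head is trained with
binary cross-entropy, weighted 1:1 with the segmentation loss by default.
Optimization uses Adam (lr 1e-3 by default, no schedule).  Runs are
reproducible given the seeds: weights come from the network config seed and
batch order from the training seed, and all arithmetic is plain NumPy.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from . import autograd as ag
from .autograd import Tensor
from .network import CariesUNet, NetworkConfig

__all__ = [
    "normalize_volume",
    "segmentation_loss",
    "soft_jaccard_index",
    "train",
    "CariesSegmenter",
]


def normalize_volume(volume: np.ndarray) -> np.ndarray:
    """Per-volume z-score normalization applied before the network."""
    v = np.asarray(volume, np.float32)
    return (v - v.mean()) / (v.std() + 1e-8)


def _check_binary(target: np.ndarray) -> np.ndarray:
    t = np.asarray(target)
    if t.dtype != bool and not np.all(np.isin(np.unique(t), (0, 1))):
        raise ValueError("segmentation target must be binary (0/1)")
    return t.astype(np.float64 if t.dtype == np.float64 else np.float32)


def segmentation_loss(pred_prob, target) -> float:
    """(1 - soft Jaccard) + voxel-mean binary cross-entropy, as a float."""
    t = _check_binary(target)
    p = pred_prob if isinstance(pred_prob, Tensor) else Tensor(np.asarray(pred_prob))
    if p.data.shape != t.shape:
        raise ValueError(f"shape mismatch: pred {p.data.shape} vs target {t.shape}")
    return float(_segmentation_loss_t(p, t).data)


def _segmentation_loss_t(pred: Tensor, target: np.ndarray) -> Tensor:
    return (1.0 - ag.soft_jaccard(pred, target)) + ag.bce_mean(pred, target)


def soft_jaccard_index(pred_prob: np.ndarray, target: np.ndarray) -> float:
    """Soft Jaccard index (eps-smoothed IoU) between probabilities and a mask."""
    return float(ag.soft_jaccard(Tensor(np.asarray(pred_prob)),
                                 _check_binary(target)).data)


def train(
    network: CariesUNet,
    dataset,
    n_steps: int = 200,
    batch_size: int = 2,
    lr: float = 1e-3,
    seed: int = 0,
    cls_loss_weight: float = 1.0,
    normalize: bool = True,
    callback=None,
):
    """Train in place; returns the per-step loss history.

    ``dataset`` is a sequence of ``(volume, lesion_mask, tooth_label)``
    triples; ``tooth_label`` may be None, in which case it is derived from
    the mask.  A NaN loss aborts with a diagnostic.
    """
    dataset = list(dataset)
    if not dataset:
        raise ValueError("training dataset is empty")
    prepared = []
    for vol, mask, label in dataset:
        v = normalize_volume(vol) if normalize else np.asarray(vol, np.float32)
        m = _check_binary(mask)
        if label is None:
            label = float(np.asarray(mask).any())
        prepared.append((v, m, float(label)))

    rng = np.random.default_rng(seed)
    opt = ag.Adam(network.params, lr=lr)
    history = []
    n = len(prepared)
    for step in range(n_steps):
        idx = rng.choice(n, size=min(batch_size, n), replace=False)
        x = np.stack([prepared[i][0] for i in idx])[:, None]
        m = np.stack([prepared[i][1] for i in idx])[:, None]
        y = np.array([[prepared[i][2]] for i in idx], np.float32)

        out = network.forward(x)
        seg = _segmentation_loss_t(out["lesion_prob"], m)
        cls = ag.bce_mean(out["tooth_prob"], y)
        loss = seg + cls_loss_weight * cls
        value = float(loss.data)
        if not np.isfinite(value):
            raise RuntimeError(
                f"non-finite loss at step {step}: seg={float(seg.data)} "
                f"cls={float(cls.data)}; aborting training"
            )
        opt.zero_grad()
        loss.backward()
        opt.step()
        history.append(value)
        if callback is not None:
            callback(step, value)
    return history


class CariesSegmenter(BaseEstimator):
    """Attention 3D U-Net caries segmenter with a scikit-learn interface.

    Parameters mirror :class:`NetworkConfig` plus the training
    hyperparameters.  ``fit`` expects ``X`` of shape (n_samples, D, H, W)
    (tooth volumes) and ``y`` of the same shape (binary lesion masks); the
    tooth-level label is derived from each mask.  Spatial dims must be
    divisible by ``2 ** (n_levels - 1)``.

    Attributes
    ----------
    network_ : CariesUNet
        The trained network.
    loss_history_ : list of float
        Per-step training loss.
    """

    def __init__(self, n_levels=3, base_channels=4, leaky_slope=0.01,
                 deep_supervision=True, attention_gates=True, n_steps=300,
                 batch_size=2, lr=1e-3, cls_loss_weight=1.0, seed=0):
        self.n_levels = n_levels
        self.base_channels = base_channels
        self.leaky_slope = leaky_slope
        self.deep_supervision = deep_supervision
        self.attention_gates = attention_gates
        self.n_steps = n_steps
        self.batch_size = batch_size
        self.lr = lr
        self.cls_loss_weight = cls_loss_weight
        self.seed = seed

    def _network_config(self) -> NetworkConfig:
        return NetworkConfig(
            n_levels=self.n_levels,
            base_channels=self.base_channels,
            leaky_slope=self.leaky_slope,
            deep_supervision=self.deep_supervision,
            attention_gates=self.attention_gates,
            seed=self.seed,
        )

    def fit(self, X, y):
        X = np.asarray(X, np.float32)
        y = np.asarray(y)
        if X.ndim != 4 or y.shape != X.shape:
            raise ValueError(
                f"expected X (n, D, H, W) and y of the same shape, got "
                f"{X.shape} and {y.shape}"
            )
        self.network_ = CariesUNet(self._network_config())
        dataset = [(X[i], y[i].astype(bool), None) for i in range(len(X))]
        self.loss_history_ = train(
            self.network_, dataset, n_steps=self.n_steps,
            batch_size=self.batch_size, lr=self.lr, seed=self.seed,
            cls_loss_weight=self.cls_loss_weight,
        )
        return self

    def _check_fitted(self):
        if not hasattr(self, "network_"):
            raise AttributeError("this CariesSegmenter instance is not fitted yet")

    def predict_proba(self, X) -> np.ndarray:
        """Voxelwise lesion probabilities, shape (n, D, H, W)."""
        self._check_fitted()
        X = np.asarray(X, np.float32)
        return np.stack([
            self.network_.predict_volume(normalize_volume(x)).lesion_prob for x in X
        ])

    def tooth_proba(self, X) -> np.ndarray:
        """Tooth-level caries probabilities, shape (n,)."""
        self._check_fitted()
        X = np.asarray(X, np.float32)
        return np.array([
            self.network_.predict_volume(normalize_volume(x)).tooth_prob for x in X
        ])

    def predict(self, X) -> np.ndarray:
        """Binary lesion masks at the 0.5 probability cutoff."""
        return self.predict_proba(X) >= 0.5

    def score(self, X, y) -> float:
        """Mean soft-Jaccard index over samples (higher is better)."""
        probs = self.predict_proba(X)
        y = np.asarray(y)
        return float(np.mean([
            soft_jaccard_index(p, m.astype(bool)) for p, m in zip(probs, y)
        ]))
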