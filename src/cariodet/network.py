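"""Attention 3D U-Net with deep supervision and a tooth-level classification head.

Architecture summary (fully convolutional, NCDHW):

* encoder — one 3x3x3 convolution per level; levels are connected by 3x3x3
  convolutions with stride 2, halving the resolution and doubling the channel
  count; every convolution is followed by instance normalization and a leaky
  ReLU (batch statistics are unreliable at batch sizes of 1-2 volumes),
* decoder — nearest-neighbour x2 upsampling; the corresponding encoder skip
  is gated by an additive attention gate (one scalar coefficient in [0, 1]
  per spatial location, broadcast over channels) and concatenated; each
  decoder block is a 3x3x3 convolution followed by a 1x1x1 convolution that
  halves the feature-map count,
* deep supervision — a 1-channel segmentation map at every decoder level,
  upscaled (nearest) to full resolution and combined by element-wise
  summation before the final sigmoid,
* classification head — global average pooling of the deepest features, a
  dense layer and a sigmoid giving the probability that the tooth is carious.

Weights are freshly initialized (He-style) from the config seed; no
pre-trained weights are involved.  The default width (8 base channels,
4 levels) is sized for CPU training on phantom volumes and is configurable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .errors import ConfigurationError

__all__ = ["NetworkConfig", "CariesPrediction", "CariesUNet", "build_network",
           "attention_gate_forward"]


@dataclass
class NetworkConfig:
    """Width/depth and feature flags of the caries localization network."""

    n_levels: int = 4
    base_channels: int = 8
    leaky_slope: float = 0.01
    deep_supervision: bool = True
    attention_gates: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.n_levels < 2:
            raise ConfigurationError(f"n_levels must be >= 2, got {self.n_levels}")
        if self.base_channels < 1:
            raise ConfigurationError(f"base_channels must be >= 1, got {self.base_channels}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        return cls(**d)


@dataclass
class CariesPrediction:
    """Voxelwise lesion probabilities plus the tooth-level caries probability."""

    lesion_prob: np.ndarray
    tooth_prob: float

    def __post_init__(self):
        lp = np.asarray(self.lesion_prob)
        if lp.min() < 0.0 or lp.max() > 1.0:
            raise ValueError("lesion probabilities must lie in [0, 1]")
        if not 0.0 <= self.tooth_prob <= 1.0:
            raise ValueError("tooth probability must lie in [0, 1]")
        self.lesion_prob = lp


def _he_conv(rng, cout, cin, k, dtype=np.float32):
    fan_in = cin * k ** 3
    w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(cout, cin, k, k, k))
    return w.astype(dtype)


class _Conv:
    def __init__(self, rng, cin, cout, k, stride, params, name):
        self.stride = stride
        self.w = Tensor(_he_conv(rng, cout, cin, k), requires_grad=True, name=f"{name}.w")
        self.b = Tensor(np.zeros(cout, np.float32), requires_grad=True, name=f"{name}.b")
        params += [self.w, self.b]

    def __call__(self, x):
        return ag.conv3d(x, self.w, self.b, stride=self.stride)


class _Norm:
    def __init__(self, c, params, name):
        self.g = Tensor(np.ones(c, np.float32), requires_grad=True, name=f"{name}.g")
        self.b = Tensor(np.zeros(c, np.float32), requires_grad=True, name=f"{name}.b")
        params += [self.g, self.b]

    def __call__(self, x):
        return ag.instance_norm(x, self.g, self.b)


class _AttentionGate:
    """Additive attention gate (per-voxel scalar coefficient, channel-broadcast).

    The skip is projected to the gating resolution by a strided 1x1x1
    convolution, added to the projected gate signal, passed through a leaky
    ReLU and a 1-channel 1x1x1 convolution with sigmoid, and the resulting
    coefficient grid is upscaled (nearest) back to the skip resolution.
    """

    def __init__(self, rng, c_skip, c_gate, slope, params, name):
        c_int = max(1, c_skip // 2)
        self.slope = slope
        self.theta = _Conv(rng, c_skip, c_int, 1, 2, params, f"{name}.theta")
        self.phi = _Conv(rng, c_gate, c_int, 1, 1, params, f"{name}.phi")
        self.psi = _Conv(rng, c_int, 1, 1, 1, params, f"{name}.psi")

    def __call__(self, skip, gate):
        if tuple(2 * np.array(gate.shape[2:])) != tuple(skip.shape[2:]):
            raise ValueError(
                f"gate spatial shape {gate.shape[2:]} incompatible with skip "
                f"{skip.shape[2:]} (must be exactly half)"
            )
        q = ag.leaky_relu(self.theta(skip) + self.phi(gate), self.slope)
        alpha = ag.sigmoid(self.psi(q))          # (N, 1, d/2, h/2, w/2)
        alpha_up = ag.upsample_nearest2(alpha)   # (N, 1, d, h, w)
        return ag.mul(skip, alpha_up), alpha_up


def attention_gate_forward(gate_module: _AttentionGate, skip: np.ndarray,
                           gating: np.ndarray):
    """Run one attention gate on raw arrays; returns (gated skip, coefficients)."""
    out, alpha = gate_module(Tensor(skip), Tensor(gating))
    return out.data, alpha.data


class CariesUNet:
    """The caries localization network (see module docstring)."""

    def __init__(self, config: NetworkConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        P: list[Tensor] = []
        L = config.n_levels
        ch = [config.base_channels * 2 ** l for l in range(L)]
        self.channels = ch

        self.enc_conv, self.enc_norm = [], []
        for l in range(L):
            cin = 1 if l == 0 else ch[l - 1]
            stride = 1 if l == 0 else 2
            self.enc_conv.append(_Conv(rng, cin, ch[l], 3, stride, P, f"enc{l}"))
            self.enc_norm.append(_Norm(ch[l], P, f"enc{l}.norm"))

        self.gates, self.dec3, self.dec3n, self.dec1, self.dec1n, self.seg = \
            {}, {}, {}, {}, {}, {}
        for l in range(L - 2, -1, -1):
            if config.attention_gates:
                self.gates[l] = _AttentionGate(rng, ch[l], ch[l + 1],
                                               config.leaky_slope, P, f"att{l}")
            cat = ch[l + 1] + ch[l]
            self.dec3[l] = _Conv(rng, cat, 2 * ch[l], 3, 1, P, f"dec{l}.c3")
            self.dec3n[l] = _Norm(2 * ch[l], P, f"dec{l}.c3n")
            self.dec1[l] = _Conv(rng, 2 * ch[l], ch[l], 1, 1, P, f"dec{l}.c1")
            self.dec1n[l] = _Norm(ch[l], P, f"dec{l}.c1n")
            if config.deep_supervision or l == 0:
                self.seg[l] = _Conv(rng, ch[l], 1, 1, 1, P, f"seg{l}")

        self.cls_w = Tensor(
            rng.normal(0.0, np.sqrt(1.0 / ch[-1]), size=(ch[-1], 1)).astype(np.float32),
            requires_grad=True, name="cls.w")
        self.cls_b = Tensor(np.zeros(1, np.float32), requires_grad=True, name="cls.b")
        P += [self.cls_w, self.cls_b]
        self.params = P

    # -- bookkeeping -------------------------------------------------------
    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.params))

    def state_dict(self) -> dict:
        return {p.name: p.data.copy() for p in self.params}

    def load_state_dict(self, state: dict) -> None:
        for p in self.params:
            p.data = np.array(state[p.name], dtype=p.data.dtype)

    def save(self, weights_path: str, config_path: str | None = None) -> None:
        np.savez(weights_path, **self.state_dict())
        if config_path is not None:
            with open(config_path, "w") as fh:
                json.dump(self.config.to_dict(), fh, indent=2)

    @classmethod
    def load(cls, weights_path: str, config_path: str) -> "CariesUNet":
        with open(config_path) as fh:
            config = NetworkConfig.from_dict(json.load(fh))
        net = cls(config)
        with np.load(weights_path) as npz:
            net.load_state_dict({k: npz[k] for k in npz.files})
        return net

    # -- forward -----------------------------------------------------------
    def _check_shape(self, shape):
        div = 2 ** (self.config.n_levels - 1)
        if any(s % div for s in shape):
            raise ConfigurationError(
                f"input spatial shape {tuple(shape)} must be divisible by "
                f"{div} per axis for {self.config.n_levels} levels"
            )

    def forward(self, x) -> dict:
        """Forward pass on an (N, 1, D, H, W) array or Tensor.

        Returns a dict with Tensors 'lesion_prob' (N, 1, D, H, W) and
        'tooth_prob' (N,), plus 'attention': the coefficient grids per level.
        """
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x))
        if x.data.ndim != 5 or x.data.shape[1] != 1:
            raise ValueError(f"expected (N, 1, D, H, W) input, got {x.data.shape}")
        self._check_shape(x.data.shape[2:])
        cfg = self.config
        L = cfg.n_levels
        act = lambda t: ag.leaky_relu(t, cfg.leaky_slope)

        enc = []
        h = x
        for l in range(L):
            h = act(self.enc_norm[l](self.enc_conv[l](h)))
            enc.append(h)

        attention = {}
        dec = {L - 1: enc[L - 1]}
        for l in range(L - 2, -1, -1):
            gate = dec[l + 1]
            skip = enc[l]
            if cfg.attention_gates:
                skip, alpha = self.gates[l](skip, gate)
                attention[l] = alpha.data
            up = ag.upsample_nearest2(gate)
            h = ag.concat(up, skip, axis=1)
            h = act(self.dec3n[l](self.dec3[l](h)))
            h = act(self.dec1n[l](self.dec1[l](h)))
            dec[l] = h

        if cfg.deep_supervision:
            logits = []
            for l, head in self.seg.items():
                s = head(dec[l])
                for _ in range(l):
                    s = ag.upsample_nearest2(s)
                logits.append(s)
            seg_logits = ag.add_n(logits)
        else:
            seg_logits = self.seg[0](dec[0])
        lesion_prob = ag.sigmoid(seg_logits)

        pooled = ag.global_avg_pool(dec[L - 1])
        tooth_logit = ag.dense(pooled, self.cls_w, self.cls_b)
        tooth_prob = ag.sigmoid(tooth_logit)

        return {
            "lesion_prob": lesion_prob,
            "tooth_prob": tooth_prob,
            "attention": attention,
        }

    def predict_volume(self, volume: np.ndarray) -> CariesPrediction:
        """Predict for one normalized tooth volume of shape (D, H, W)."""
        out = self.forward(np.asarray(volume, np.float32)[None, None])
        return CariesPrediction(
            lesion_prob=out["lesion_prob"].data[0, 0],
            tooth_prob=float(out["tooth_prob"].data.ravel()[0]),
        )


def build_network(config: NetworkConfig) -> CariesUNet:
    """Instantiate a freshly initialized network from a config."""
    return CariesUNet(config)
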