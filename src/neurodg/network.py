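"""3D attention classifier: conv encoder, class-wise attention gate, GAP head.

The network mirrors the standard encoder/attention/classifier decomposition
used for volumetric brain-MRI classification:

* **encoder** — a stack of (conv3x3x3 -> ReLU -> avgpool/2) stages producing a
  feature grid at ``1/downsample_factor`` of the input resolution;
* **attention module** — two parallel 3x3x3 convolutions from the features:
  one produces K feature channels ``F'`` (one per diagnostic class), the
  other, squashed through a sigmoid, produces the K class-wise attention
  gates ``M`` in [0, 1]; the module output is the elementwise product
  ``F' * M``;
* **classifier** — global average pooling of each class channel to a logit,
  followed by a softmax. Pooling over space (rather than flattening)
  preserves the spatial meaning of each class channel, which is what makes
  the attention maps interpretable and alignable with saliency priors.

All parameters are float64, initialized from a single seed; forward passes
are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = ["ModelConfig", "FeatureStack", "AttentionMaps", "AttentionNet3D"]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyper-parameters.

    ``downsample_factor`` must equal ``2 ** len(encoder_channels)`` — each
    encoder stage halves every spatial axis once.
    """

    n_classes: int = 3
    encoder_channels: tuple[int, ...] = (8, 16)
    kernel_size: int = 3
    downsample_factor: int = 4
    attention_activation: str = "sigmoid"
    seed: int = 0

    def __post_init__(self):
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.downsample_factor != 2 ** len(self.encoder_channels):
            raise ValueError(
                "downsample_factor must be 2**len(encoder_channels); "
                f"got {self.downsample_factor} with {len(self.encoder_channels)} stages"
            )
        if self.attention_activation != "sigmoid":
            raise ValueError("only the sigmoid gate parameterization is supported")
        if self.kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd")


@dataclass
class FeatureStack:
    """A batch of channel-stacked 3D feature grids, shape (N, C, d, h, w)."""

    values: np.ndarray

    def __post_init__(self):
        if self.values.ndim != 5:
            raise ValueError("FeatureStack expects a (N, C, d, h, w) array")


@dataclass
class AttentionMaps:
    """Per-sample class-wise attention gates, shape (N, K, d, h, w), in [0,1]."""

    values: np.ndarray

    def __post_init__(self):
        if self.values.ndim != 5:
            raise ValueError("AttentionMaps expects a (N, K, d, h, w) array")
        v = self.values
        if not np.isfinite(v).all():
            raise ValueError("attention values must be finite")
        if v.size and (v.min() < -1e-12 or v.max() > 1.0 + 1e-12):
            raise ValueError("attention values must lie in [0, 1]")


def _he_normal(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in = int(np.prod(shape[1:]))
    return rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)


class AttentionNet3D:
    """The classifier network. Parameters live as autodiff Tensors."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        k = config.kernel_size
        self.params: dict[str, Tensor] = {}
        c_in = 1
        for s, c_out in enumerate(config.encoder_channels):
            self.params[f"enc{s}.w"] = Tensor(_he_normal(rng, (c_out, c_in, k, k, k)), requires_grad=True)
            self.params[f"enc{s}.b"] = Tensor(np.zeros(c_out), requires_grad=True)
            c_in = c_out
        K = config.n_classes
        self.params["fprime.w"] = Tensor(_he_normal(rng, (K, c_in, k, k, k)), requires_grad=True)
        self.params["fprime.b"] = Tensor(np.zeros(K), requires_grad=True)
        self.params["attn.w"] = Tensor(_he_normal(rng, (K, c_in, k, k, k)), requires_grad=True)
        self.params["attn.b"] = Tensor(np.zeros(K), requires_grad=True)

    # -- plumbing -------------------------------------------------------
    def parameters(self) -> list[Tensor]:
        return list(self.params.values())

    def validate_finite(self) -> None:
        for name, p in self.params.items():
            if not np.isfinite(p.data).all():
                raise ValueError(f"model parameter {name!r} contains non-finite values")

    def _as_batch(self, volume: np.ndarray) -> tuple[np.ndarray, bool]:
        v = np.asarray(volume, dtype=np.float64)
        squeezed = v.ndim == 3
        if squeezed:
            v = v[None]
        if v.ndim != 4:
            raise ValueError(f"expected a (D,H,W) or (N,D,H,W) volume, got shape {v.shape}")
        if not np.isfinite(v).all():
            raise ValueError("input volume contains non-finite values")
        f = self.config.downsample_factor
        if any(s % f for s in v.shape[1:]):
            raise ValueError(
                f"spatial shape {v.shape[1:]} is not divisible by downsample_factor {f}"
            )
        return v, squeezed

    # -- differentiable forward ----------------------------------------
    #: Input intensities are expected in [0, 1]; the forward pass centers
    #: them at this value so first-layer activations are zero-mean.
    INPUT_CENTER = 0.5

    def forward_graph(self, x: Tensor) -> dict[str, Tensor]:
        """Full forward pass on a (N, 1, D, H, W) input tensor.

        Returns every intermediate the losses and the attribution need.
        """
        h = x + Tensor(np.float64(-self.INPUT_CENTER))
        for s in range(len(self.config.encoder_channels)):
            h = ad.conv3d(h, self.params[f"enc{s}.w"], self.params[f"enc{s}.b"])
            h = ad.relu(h)
            h = ad.avg_pool3d(h, 2)
        f_prime = ad.conv3d(h, self.params["fprime.w"], self.params["fprime.b"])
        attention = ad.sigmoid(ad.conv3d(h, self.params["attn.w"], self.params["attn.b"]))
        attended = f_prime * attention
        logits = attended.mean(axis=(2, 3, 4))  # GAP: (N, K)
        return {
            "features": h,
            "f_prime": f_prime,
            "attention": attention,
            "attended": attended,
            "logits": logits,
            "log_probs": ad.log_softmax(logits),
        }

    # -- inference-time API ---------------------------------------------
    def encode(self, volume: np.ndarray) -> FeatureStack:
        """Encoder features at 1/downsample_factor resolution."""
        self.validate_finite()
        v, _ = self._as_batch(volume)
        h = Tensor(v[:, None] - self.INPUT_CENTER)
        for s in range(len(self.config.encoder_channels)):
            h = ad.avg_pool3d(ad.relu(ad.conv3d(h, self.params[f"enc{s}.w"], self.params[f"enc{s}.b"])), 2)
        return FeatureStack(h.data)

    def attend(self, features: FeatureStack | np.ndarray):
        """Attention gates and gated features from encoder output.

        Returns ``(AttentionMaps M, FeatureStack attended, FeatureStack F')``
        with ``attended = F' * M`` elementwise.
        """
        f = features.values if isinstance(features, FeatureStack) else np.asarray(features, dtype=np.float64)
        if f.ndim != 5:
            raise ValueError("attend expects (N, C, d, h, w) features")
        c_expected = self.config.encoder_channels[-1]
        if f.shape[1] != c_expected:
            raise ValueError(f"feature stack has {f.shape[1]} channels, expected {c_expected}")
        ft = Tensor(f)
        f_prime = ad.conv3d(ft, self.params["fprime.w"], self.params["fprime.b"])
        m = ad.sigmoid(ad.conv3d(ft, self.params["attn.w"], self.params["attn.b"]))
        attended = f_prime.data * m.data
        return AttentionMaps(m.data), FeatureStack(attended), FeatureStack(f_prime.data)

    def classify(self, attended: FeatureStack | np.ndarray) -> np.ndarray:
        """Softmax class probabilities from gated features via GAP."""
        a = attended.values if isinstance(attended, FeatureStack) else np.asarray(attended, dtype=np.float64)
        if a.ndim != 5 or a.shape[1] != self.config.n_classes:
            raise ValueError(f"classify expects (N, K, d, h, w) with K={self.config.n_classes}")
        logits = a.mean(axis=(2, 3, 4))
        logits = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        return e / e.sum(axis=1, keepdims=True)

    def predict_proba(self, volumes: np.ndarray) -> np.ndarray:
        features = self.encode(volumes)
        _, attended, _ = self.attend(features)
        return self.classify(attended)

    def attention_maps(self, volumes: np.ndarray) -> np.ndarray:
        """Class-wise attention gates for a batch, shape (N, K, d, h, w)."""
        m, _, _ = self.attend(self.encode(volumes))
        return m.values

    # -- attribution hook -----------------------------------------------
    def score_and_grad(self, volume: np.ndarray, target_class: int) -> tuple[float, np.ndarray]:
        """Pre-softmax logit of ``target_class`` and its input gradient.

        The logit (not the softmax output) is the attribution score: its
        gradients do not saturate when the classifier is confident.
        """
        self.validate_finite()
        v, _ = self._as_batch(volume)
        if v.shape[0] != 1:
            raise ValueError("score_and_grad expects a single volume")
        x = Tensor(v[:, None], requires_grad=True)
        out = self.forward_graph(x)
        score = ad.gather_rows(out["logits"], np.array([target_class])).sum()
        score.backward()
        return float(score.data), x.grad[0, 0].copy()

    # -- checkpointing ---------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, p in self.params.items():
            if k not in state:
                raise KeyError(f"checkpoint missing parameter {k!r}")
            if state[k].shape != p.data.shape:
                raise ValueError(f"checkpoint parameter {k!r} has shape {state[k].shape}, expected {p.data.shape}")
            p.data = np.asarray(state[k], dtype=np.float64).copy()

    def save(self, path) -> None:
        arrays = self.state_dict()
        arrays["__config__"] = np.frombuffer(
            _config_to_json(self.config).encode(), dtype=np.uint8
        )
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "AttentionNet3D":
        with np.load(path) as npz:
            cfg = _config_from_json(bytes(npz["__config__"]).decode())
            net = cls(cfg)
            net.load_state_dict({k: npz[k] for k in npz.files if k != "__config__"})
        return net


def _config_to_json(cfg: ModelConfig) -> str:
    import json

    d = {
        "n_classes": cfg.n_classes,
        "encoder_channels": list(cfg.encoder_channels),
        "kernel_size": cfg.kernel_size,
        "downsample_factor": cfg.downsample_factor,
        "attention_activation": cfg.attention_activation,
        "seed": cfg.seed,
    }
    return json.dumps(d, sort_keys=True)


def _config_from_json(s: str) -> ModelConfig:
    import json

    d = json.loads(s)
    d["encoder_channels"] = tuple(d["encoder_channels"])
    return ModelConfig(**d)
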