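"""Two-stage training with attention-to-prior alignment.

Stage 1 fits a baseline classifier with class-weighted cross-entropy (WCE);
its correct predictions seed the class-wise saliency priors (see
:mod:`neurodg.priors`). Stage 2 trains a fresh, independent model on the
combined objective

    L = L_WCE + lambda * L_sim,

where ``L_sim`` sums, over classes k, the L2 distance between each sample's
class-k attention map M_{i,k} and the class-k prior SHAP_k, mean-reduced
over the minibatch. Class weights are inverse class counts, countering the
NC > MCI > AD imbalance typical of dementia cohorts. Training uses gradient
accumulation so a small micro-batch can simulate a larger effective batch.

The trainer is exposed as a scikit-learn style estimator,
:class:`AttentionGuidedClassifier`; :func:`train_stage1` and
:func:`train_stage2` are thin wrappers over it.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from . import autodiff as ad
from .autodiff import Adam, Tensor
from .network import AttentionNet3D, ModelConfig
from .priors import ClassPrior, resample_grid

__all__ = [
    "AugmentFlags",
    "TrainConfig",
    "class_weights",
    "wce_loss",
    "sim_loss",
    "total_loss",
    "augment",
    "mixup_batch",
    "AttentionGuidedClassifier",
    "train_stage1",
    "train_stage2",
    "posthoc_sim_loss",
]

_EPS = 1e-12


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AugmentFlags:
    """Which stochastic augmentations to apply (intensity rescale is always on)."""

    contrast: bool = False
    bias_field: bool = False
    crop_upsample: bool = False

    def any(self) -> bool:
        return self.contrast or self.bias_field or self.crop_upsample


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyper-parameters.

    ``lam`` defaults to 5e-5, the value reported for full-resolution brain
    volumes with an unnormalized L2 similarity term; at coarser desk-scale
    resolutions a larger value is appropriate (see docs/methods.md).
    ``micro_batch * accumulation_steps`` is the effective batch size
    (2 x 8 = 16 by default).
    """

    lam: float = 5e-5
    epochs: int = 10
    steps_per_epoch: int | None = None
    micro_batch: int = 2
    accumulation_steps: int = 8
    learning_rate: float = 1e-3
    mixup_alpha: float = 0.0
    sim_scope: str = "all_classes"  # or "true_class_only"
    prior_scale: str = "raw"  # or "unit": align against [-1,1]-scaled priors
    normalize_by_voxels: bool = False
    augmentations: AugmentFlags = AugmentFlags()
    seed: int = 0

    def __post_init__(self):
        if self.lam < 0:
            raise ValueError("lam must be >= 0")
        if self.accumulation_steps < 1:
            raise ValueError("accumulation_steps must be >= 1")
        if self.sim_scope not in ("all_classes", "true_class_only"):
            raise ValueError(f"unknown sim_scope {self.sim_scope!r}")
        if self.prior_scale not in ("raw", "unit"):
            raise ValueError(f"unknown prior_scale {self.prior_scale!r}")

    @property
    def effective_batch(self) -> int:
        return self.micro_batch * self.accumulation_steps


# ---------------------------------------------------------------------------
# loss primitives (array-facing; the training loop uses graph twins)
# ---------------------------------------------------------------------------

def class_weights(labels: np.ndarray, n_classes: int | None = None) -> np.ndarray:
    """Inverse-count class weights, w_k = 1 / count_k (unnormalized).

    Every class must be present; a missing class is an error naming it.
    """
    labels = np.asarray(labels, dtype=int)
    K = int(n_classes) if n_classes is not None else int(labels.max()) + 1
    counts = np.bincount(labels, minlength=K)
    missing = np.flatnonzero(counts == 0)
    if missing.size:
        raise ValueError(f"class(es) {missing.tolist()} absent from the training labels")
    return 1.0 / counts


def wce_loss(probabilities: np.ndarray, labels: np.ndarray, weights: np.ndarray) -> float:
    """Weighted cross-entropy, mean-reduced over the minibatch.

    ``labels`` may be integer class ids or one-hot / soft rows. Predicted
    probabilities at the true class are clamped below at 1e-12.
    """
    p = np.asarray(probabilities, dtype=np.float64)
    y = np.asarray(labels)
    w = np.asarray(weights, dtype=np.float64)
    if y.ndim == 1:
        onehot = np.zeros_like(p)
        onehot[np.arange(len(y)), y.astype(int)] = 1.0
        y = onehot
    sample_w = y @ w
    ll = (y * np.log(np.clip(p, _EPS, None))).sum(axis=1)
    return float(-(sample_w * ll).mean())


def _norms(attention: np.ndarray, prior_stack: np.ndarray, normalize_by_voxels: bool) -> np.ndarray:
    diff = attention - prior_stack[None]
    sq = (diff * diff).sum(axis=(2, 3, 4))
    if normalize_by_voxels:
        sq = sq / diff[0, 0].size
    return np.sqrt(sq)  # (N, K)


def sim_loss(attention: np.ndarray, priors: Sequence[ClassPrior],
             normalize_by_voxels: bool = False, sim_scope: str = "all_classes",
             labels: np.ndarray | None = None) -> float:
    """Attention-to-prior similarity loss.

    For each sample i and class k, the L2 norm of ``M_{i,k} - SHAP_k`` over
    voxels; summed over the K classes and mean-reduced over the batch. Zero
    iff every attention channel equals its class prior. Priors must already
    live at attention resolution and all be present.
    """
    att = np.asarray(attention, dtype=np.float64)
    if att.ndim == 4:
        att = att[None]
    K = att.shape[1]
    stack = _stack_priors(priors, K, att.shape[2:])
    norms = _norms(att, stack, normalize_by_voxels)
    if sim_scope == "true_class_only":
        if labels is None:
            raise ValueError("sim_scope='true_class_only' requires labels")
        norms = norms[np.arange(len(labels)), np.asarray(labels, dtype=int)][:, None]
    return float(norms.sum(axis=1).mean())


def _stack_priors(priors: Sequence[ClassPrior], K: int, shape) -> np.ndarray:
    by_id = {p.class_id: p for p in priors}
    grids = []
    for k in range(K):
        p = by_id.get(k)
        if p is None or p.absent:
            raise ValueError(f"prior for class {k} is absent; alignment cannot run")
        if tuple(p.grid.shape) != tuple(shape):
            raise ValueError(
                f"prior for class {k} has shape {p.grid.shape}, expected {tuple(shape)}; "
                "resample priors to attention resolution first"
            )
        grids.append(p.grid)
    return np.stack(grids)


def total_loss(wce: float, sim: float, lam: float) -> float:
    """Combined objective: wce + lam * sim; lam = 0 recovers wce exactly."""
    return float(wce) + float(lam) * float(sim)


# ---------------------------------------------------------------------------
# augmentation and mixup
# ---------------------------------------------------------------------------

def _rescale_unit(v: np.ndarray) -> np.ndarray:
    """Intensity scaling to [0, 1]; a no-op for volumes already inside it."""
    lo, hi = float(v.min()), float(v.max())
    if lo >= 0.0 and hi <= 1.0:
        return v
    if hi == lo:
        return np.clip(v, 0.0, 1.0)
    return (v - lo) / (hi - lo)


def augment(volume: np.ndarray, flags: AugmentFlags, seed: int) -> np.ndarray:
    """Stochastic intensity/spatial augmentation of one volume.

    Applies, in order and only where flagged: random contrast (gamma),
    random multiplicative bias field, random spatial crop followed by
    trilinear upsampling back to the input shape; then always rescales
    intensities into [0, 1] (idempotent on volumes already in range).
    Deterministic per seed.
    """
    from scipy.ndimage import gaussian_filter

    v = np.asarray(volume, dtype=np.float64).copy()
    rng = np.random.default_rng(seed)
    if flags.contrast:
        gamma = float(np.exp(rng.uniform(np.log(0.7), np.log(1.5))))
        v = np.clip(v, 0.0, None) ** gamma
    if flags.bias_field:
        f = gaussian_filter(rng.standard_normal(v.shape), sigma=max(min(v.shape) / 4.0, 1.0))
        span = f.max() - f.min()
        if span > 0:
            f = 0.85 + 0.30 * (f - f.min()) / span  # bias in [0.85, 1.15]
            v = v * f
    if flags.crop_upsample:
        crop = [max(2, int(round(0.8 * s))) for s in v.shape]
        origin = [int(rng.integers(0, s - c + 1)) for s, c in zip(v.shape, crop)]
        sub = v[tuple(slice(o, o + c) for o, c in zip(origin, crop))]
        v = resample_grid(sub, v.shape)
    return _rescale_unit(v)


def mixup_batch(x_a: np.ndarray, y_a: np.ndarray, x_b: np.ndarray, y_b: np.ndarray,
                alpha: float = 0.2, seed: int = 0,
                lam_mix: float | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Convex combination of two example batches and their one-hot labels.

    The mixing coefficient is drawn once per call from Beta(alpha, alpha)
    (default alpha = 0.2) unless ``lam_mix`` forces it.
    """
    if alpha <= 0 and lam_mix is None:
        raise ValueError("alpha must be > 0")
    if lam_mix is None:
        lam_mix = float(np.random.default_rng(seed).beta(alpha, alpha))
    x = lam_mix * np.asarray(x_a, dtype=np.float64) + (1.0 - lam_mix) * np.asarray(x_b, dtype=np.float64)
    y = lam_mix * np.asarray(y_a, dtype=np.float64) + (1.0 - lam_mix) * np.asarray(y_b, dtype=np.float64)
    return x, y


def _one_hot(labels: np.ndarray, K: int) -> np.ndarray:
    y = np.zeros((len(labels), K))
    y[np.arange(len(labels)), np.asarray(labels, dtype=int)] = 1.0
    return y


# ---------------------------------------------------------------------------
# graph-side loss and the accumulation step
# ---------------------------------------------------------------------------

def _graph_losses(net: AttentionNet3D, xb: np.ndarray, yb: np.ndarray,
                  weights: np.ndarray, lam: float,
                  prior_stack: np.ndarray | None, sim_scope: str,
                  normalize_by_voxels: bool):
    """Build the combined loss graph for one micro-batch.

    ``yb`` is one-hot (possibly soft, under mixup). Returns
    ``(total Tensor, wce value, sim value)``.
    """
    x = Tensor(xb[:, None])
    out = net.forward_graph(x)
    logp = out["log_probs"]
    sample_w = Tensor(yb @ weights)  # (N,)
    wce = -((Tensor(yb) * logp).sum(axis=1) * sample_w).mean()
    if prior_stack is not None:
        diff = out["attention"] - Tensor(prior_stack[None])
        sq = (diff * diff).sum(axis=(2, 3, 4))  # (N, K)
        if normalize_by_voxels:
            sq = sq * (1.0 / prior_stack[0].size)
        norms = ad.sqrt0(sq)
        if sim_scope == "true_class_only":
            hard = yb.argmax(axis=1)
            norms = ad.gather_rows(norms, hard).reshape(-1, 1)
        sim = norms.sum(axis=1).mean()
        total = wce + Tensor(np.float64(lam)) * sim
        return total, float(wce.data), float(sim.data)
    return wce, float(wce.data), 0.0


def accumulate_and_step(net: AttentionNet3D, opt: Adam,
                        micro_batches: Sequence[tuple[np.ndarray, np.ndarray]],
                        weights: np.ndarray, lam: float,
                        prior_stack: np.ndarray | None,
                        sim_scope: str = "all_classes",
                        normalize_by_voxels: bool = False) -> dict[str, float]:
    """One optimizer update from ``len(micro_batches)`` accumulated micro-batches.

    Each micro-batch loss is mean-reduced internally and contributes with
    weight 1/A, so A equal micro-batches reproduce (to float rounding) the
    gradient of one batch of A * micro_batch samples.
    """
    A = len(micro_batches)
    opt.zero_grad()
    wces, sims, totals = [], [], []
    for xb, yb in micro_batches:
        loss, wce_v, sim_v = _graph_losses(net, xb, yb, weights, lam,
                                           prior_stack, sim_scope, normalize_by_voxels)
        (loss * (1.0 / A)).backward()
        wces.append(wce_v)
        sims.append(sim_v)
        totals.append(float(loss.data))
    record = {
        "wce": float(np.mean(wces)),
        "sim": float(np.mean(sims)),
        "total": float(np.mean(totals)),
    }
    if not np.isfinite(record["total"]):
        raise RuntimeError(
            f"training diverged: non-finite loss {record} — "
            "lower the learning rate or inspect the input scaling"
        )
    opt.step()
    return record


# ---------------------------------------------------------------------------
# the estimator
# ---------------------------------------------------------------------------

class AttentionGuidedClassifier(BaseEstimator, ClassifierMixin):
    """3D volumetric classifier with optional attention-to-prior alignment.

    With ``priors=None`` (or ``lam=0``) this is the stage-1 baseline trained
    on weighted cross-entropy alone; passing the class priors built from a
    baseline model and ``lam > 0`` gives the stage-2, disease-informed model.

    Parameters
    ----------
    model_config : ModelConfig or None
        Architecture; default is a two-stage encoder (8, 16 channels),
        downsampling by 4.
    lam : float
        Weight of the similarity loss in the combined objective.
    priors : sequence of ClassPrior or None
        Raw class priors at input resolution; resampled internally to
        attention resolution. Required (all K present) when ``lam > 0``.
    sim_scope : {"all_classes", "true_class_only"}
        Whether every attention channel is aligned to its class prior, or
        only the channel matching the sample's label.
    random_state : int
        Single seed for parameter init, shuffling, augmentation and mixup.

    Attributes
    ----------
    net_ : AttentionNet3D
        The trained network (best validation macro-F1 checkpoint when
        validation data was supplied, else the final parameters).
    history_ : dict
        Per-epoch and per-update loss/metric records, with "wce", "sim" and
        "total" components kept separate.
    classes_ : ndarray
        Class ids, 0..K-1.
    """

    def __init__(self, *, model_config: ModelConfig | None = None, lam: float = 0.0,
                 priors: Sequence[ClassPrior] | None = None, epochs: int = 10,
                 steps_per_epoch: int | None = None, micro_batch: int = 2,
                 accumulation_steps: int = 8, learning_rate: float = 1e-3,
                 mixup_alpha: float = 0.0, sim_scope: str = "all_classes",
                 prior_scale: str = "raw", normalize_by_voxels: bool = False,
                 augmentations: AugmentFlags = AugmentFlags(),
                 random_state: int = 0):
        self.model_config = model_config
        self.lam = lam
        self.priors = priors
        self.epochs = epochs
        self.steps_per_epoch = steps_per_epoch
        self.micro_batch = micro_batch
        self.accumulation_steps = accumulation_steps
        self.learning_rate = learning_rate
        self.mixup_alpha = mixup_alpha
        self.sim_scope = sim_scope
        self.prior_scale = prior_scale
        self.normalize_by_voxels = normalize_by_voxels
        self.augmentations = augmentations
        self.random_state = random_state

    # -- helpers --------------------------------------------------------
    def _validate_X(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 4:
            raise ValueError(f"X must be (n_samples, D, H, W); got shape {X.shape}")
        if not np.isfinite(X).all():
            raise ValueError("X contains non-finite values")
        return X

    def _prior_stack(self, cfg: ModelConfig, spatial: tuple[int, int, int]) -> np.ndarray | None:
        from .priors import scale_to_unit

        if self.priors is None:
            if self.lam > 0:
                raise ValueError("lam > 0 requires class priors")
            return None
        f = cfg.downsample_factor
        target = tuple(s // f for s in spatial)
        prepared = []
        for p in self.priors:
            if not p.absent and self.prior_scale == "unit" and p.scale != "unit":
                p = scale_to_unit(p)
            if not p.absent and tuple(p.grid.shape) != target:
                p = replace_grid(p, resample_grid(p.grid, target))
            prepared.append(p)
        return _stack_priors(prepared, cfg.n_classes, target)

    # -- sklearn API ----------------------------------------------------
    def fit(self, X, y, X_val=None, y_val=None):
        from .metrics import confusion, macro_f1

        X = self._validate_X(X)
        y = np.asarray(y, dtype=int)
        cfg = self.model_config or ModelConfig(seed=self.random_state)
        if cfg.seed != self.random_state:
            cfg = ModelConfig(n_classes=cfg.n_classes, encoder_channels=cfg.encoder_channels,
                              kernel_size=cfg.kernel_size, downsample_factor=cfg.downsample_factor,
                              attention_activation=cfg.attention_activation, seed=self.random_state)
        K = cfg.n_classes
        self.classes_ = np.arange(K)
        self.class_weights_ = class_weights(y, K)
        prior_stack = self._prior_stack(cfg, X.shape[1:])

        net = AttentionNet3D(cfg)
        opt = Adam(net.parameters(), lr=self.learning_rate)
        rng = np.random.default_rng(self.random_state)
        n = len(X)
        mb = self.micro_batch
        history: dict = {"epochs": [], "steps": []}
        best = (-np.inf, None)

        for epoch in range(self.epochs):
            order = rng.permutation(n)
            micro = [order[i:i + mb] for i in range(0, n, mb)]
            updates = [micro[i:i + self.accumulation_steps]
                       for i in range(0, len(micro), self.accumulation_steps)]
            if self.steps_per_epoch is not None:
                updates = updates[: self.steps_per_epoch]
            ep_records = []
            for group in updates:
                batches = []
                for idx in group:
                    xb = X[idx]
                    yb = _one_hot(y[idx], K)
                    if self.augmentations.any():
                        xb = np.stack([
                            augment(v, self.augmentations, int(rng.integers(2**31)))
                            for v in xb
                        ])
                    if self.mixup_alpha > 0:
                        perm = rng.permutation(len(idx))
                        xb, yb = mixup_batch(xb, yb, xb[perm], yb[perm],
                                             self.mixup_alpha, int(rng.integers(2**31)))
                    batches.append((xb, yb))
                rec = accumulate_and_step(net, opt, batches, self.class_weights_,
                                          self.lam, prior_stack, self.sim_scope,
                                          self.normalize_by_voxels)
                rec["epoch"] = epoch
                history["steps"].append(rec)
                ep_records.append(rec)
            ep = {
                "epoch": epoch,
                "wce": float(np.mean([r["wce"] for r in ep_records])),
                "sim": float(np.mean([r["sim"] for r in ep_records])),
                "total": float(np.mean([r["total"] for r in ep_records])),
            }
            if X_val is not None:
                pv = net.predict_proba(np.asarray(X_val, dtype=np.float64))
                yv = np.asarray(y_val, dtype=int)
                cm = confusion(yv, pv.argmax(axis=1), K)
                ep["val_macro_f1"] = macro_f1(cm)
                ep["val_accuracy"] = float((pv.argmax(axis=1) == yv).mean())
                if prior_stack is not None:
                    att = net.attention_maps(np.asarray(X_val, dtype=np.float64))
                    norms = _norms(att, prior_stack, self.normalize_by_voxels)
                    if self.sim_scope == "true_class_only":
                        norms = norms[np.arange(len(yv)), yv][:, None]
                    ep["val_sim"] = float(norms.sum(axis=1).mean())
                if ep["val_macro_f1"] > best[0]:
                    best = (ep["val_macro_f1"], net.state_dict())
            history["epochs"].append(ep)
        if best[1] is not None:
            net.load_state_dict(best[1])
        self.net_ = net
        self.history_ = history
        self.prior_stack_ = prior_stack
        return self

    def predict_proba(self, X) -> np.ndarray:
        return self.net_.predict_proba(self._validate_X(X))

    def predict(self, X) -> np.ndarray:
        return self.classes_[self.predict_proba(X).argmax(axis=1)]

    def attention_maps(self, X) -> np.ndarray:
        return self.net_.attention_maps(self._validate_X(X))


def replace_grid(prior: ClassPrior, grid: np.ndarray) -> ClassPrior:
    return ClassPrior(prior.class_id, grid, prior.n_samples_averaged,
                      scale=prior.scale, all_zero_warning=prior.all_zero_warning)


# ---------------------------------------------------------------------------
# stage wrappers
# ---------------------------------------------------------------------------

def _estimator_from_config(model_config: ModelConfig | None, tc: TrainConfig,
                           lam: float, priors) -> AttentionGuidedClassifier:
    return AttentionGuidedClassifier(
        model_config=model_config, lam=lam, priors=priors, epochs=tc.epochs,
        steps_per_epoch=tc.steps_per_epoch, micro_batch=tc.micro_batch,
        accumulation_steps=tc.accumulation_steps, learning_rate=tc.learning_rate,
        mixup_alpha=tc.mixup_alpha, sim_scope=tc.sim_scope,
        prior_scale=tc.prior_scale, normalize_by_voxels=tc.normalize_by_voxels,
        augmentations=tc.augmentations,
        random_state=tc.seed,
    )


def train_stage1(X, y, model_config: ModelConfig | None = None,
                 train_config: TrainConfig = TrainConfig(),
                 X_val=None, y_val=None) -> tuple[AttentionGuidedClassifier, dict]:
    """Stage-1 baseline: weighted cross-entropy only (no priors, no alignment)."""
    est = _estimator_from_config(model_config, train_config, lam=0.0, priors=None)
    est.fit(X, y, X_val=X_val, y_val=y_val)
    return est, est.history_


def train_stage2(X, y, priors: Sequence[ClassPrior],
                 model_config: ModelConfig | None = None,
                 train_config: TrainConfig = TrainConfig(),
                 X_val=None, y_val=None) -> tuple[AttentionGuidedClassifier, dict]:
    """Stage-2 model: a fresh network trained on WCE + lam * sim.

    All K class priors must be present (an absent prior is an error — the
    alignment stage cannot start without its target).
    """
    for p in priors:
        if p.absent:
            raise ValueError(f"prior for class {p.class_id} is absent; stage 2 cannot start")
    est = _estimator_from_config(model_config, train_config,
                                 lam=train_config.lam, priors=list(priors))
    est.fit(X, y, X_val=X_val, y_val=y_val)
    return est, est.history_


def posthoc_sim_loss(net: AttentionNet3D, X: np.ndarray, priors: Sequence[ClassPrior],
                     normalize_by_voxels: bool = False,
                     sim_scope: str = "all_classes",
                     labels: np.ndarray | None = None,
                     prior_scale: str = "raw") -> float:
    """Similarity loss of an arbitrary (e.g. stage-1) model against priors.

    Priors are (optionally unit-scaled and) resampled to the model's
    attention resolution internally, exactly as the stage-2 trainer
    prepares them, so stage-1 and stage-2 values are comparable.
    """
    from .priors import scale_to_unit

    X = np.asarray(X, dtype=np.float64)
    att = net.attention_maps(X)
    target = att.shape[2:]
    prepared = []
    for p in priors:
        if not p.absent and prior_scale == "unit" and p.scale != "unit":
            p = scale_to_unit(p)
        if not p.absent and tuple(p.grid.shape) != tuple(target):
            p = replace_grid(p, resample_grid(p.grid, target))
        prepared.append(p)
    return sim_loss(att, prepared, normalize_by_voxels, sim_scope, labels)
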