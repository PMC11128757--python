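"""Shapley-style voxel attributions and class-wise saliency priors.

A trained baseline classifier is explained per class with **expected
gradients**, a sampling estimator of Shapley values for differentiable
models: draws pair a background volume b with an interpolation coefficient
a ~ U(0,1) and average ``(x - b) * grad f_k(b + a (x - b))``. Averaging the
per-sample attribution grids over the baseline model's *correct* predictions
of class k yields the class prior SHAP_k used to supervise attention in the
second training stage.

``exact_shapley`` provides the exact (subset-enumeration) Shapley values for
small grouped problems; it is the in-package ground truth the estimator is
validated against, and satisfies the efficiency axiom to machine precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Protocol, Sequence

import numpy as np
from scipy.ndimage import map_coordinates

__all__ = [
    "AttributionConfig",
    "ClassPrior",
    "attribute",
    "exact_shapley",
    "build_class_priors",
    "scale_to_unit",
    "resample_prior",
]

MAX_EXACT_GROUPS = 16


class ScoreModel(Protocol):
    """Anything exposing a per-class score and its input gradient."""

    def score_and_grad(self, volume: np.ndarray, target_class: int) -> tuple[float, np.ndarray]:
        ...


@dataclass(frozen=True)
class AttributionConfig:
    method: str = "expected_gradients"
    n_background: int = 8
    n_draws: int = 8
    seed: int = 0

    def __post_init__(self):
        if self.method not in ("expected_gradients", "exact_shapley"):
            raise ValueError(f"unknown attribution method {self.method!r}")
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")
        if self.n_background < 1:
            raise ValueError("n_background must be >= 1")


@dataclass
class ClassPrior:
    """Averaged saliency grid for one class.

    ``grid is None`` marks an *absent* prior (the baseline model produced no
    correct prediction for the class) — deliberately distinct from an
    all-zero grid.
    """

    class_id: int
    grid: np.ndarray | None
    n_samples_averaged: int
    scale: str = "raw"  # "raw" | "unit"
    all_zero_warning: bool = False

    @property
    def absent(self) -> bool:
        return self.grid is None


def attribute(model: ScoreModel, volume: np.ndarray, target_class: int,
              background: Sequence[np.ndarray], config: AttributionConfig) -> np.ndarray:
    """Expected-gradients attribution of ``target_class`` for one volume.

    Each of ``config.n_draws`` Monte-Carlo draws picks a background volume
    and an interpolation coefficient; draws are produced by a generator
    seeded from ``config.seed`` so the estimate is deterministic. If the
    input equals its only background the attribution is identically zero.
    """
    if len(background) == 0:
        raise ValueError("background set must be nonempty")
    volume = np.asarray(volume, dtype=np.float64)
    rng = np.random.default_rng(config.seed)
    total = np.zeros_like(volume)
    for _ in range(config.n_draws):
        b = np.asarray(background[int(rng.integers(len(background)))], dtype=np.float64)
        alpha = float(rng.uniform())
        point = b + alpha * (volume - b)
        _, grad = model.score_and_grad(point, target_class)
        total += (volume - b) * grad
    return total / config.n_draws


def exact_shapley(score_fn: Callable[[np.ndarray], float], x: np.ndarray,
                  baseline: np.ndarray, groups: Sequence[np.ndarray]) -> np.ndarray:
    """Exact Shapley values over feature groups by full subset enumeration.

    ``groups`` is a sequence of index arrays into the flattened input;
    members of an absent group are replaced by the baseline's values. The
    returned attributions satisfy the efficiency axiom —
    ``sum == score_fn(x) - score_fn(baseline)`` — up to float rounding.
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    baseline = np.asarray(baseline, dtype=np.float64).ravel()
    if x.shape != baseline.shape:
        raise ValueError("x and baseline must have identical shapes")
    G = len(groups)
    if G > MAX_EXACT_GROUPS:
        raise ValueError(f"exact enumeration limited to {MAX_EXACT_GROUPS} groups, got {G}")
    idx = [np.asarray(g, dtype=np.intp) for g in groups]

    # score every coalition once
    values = np.empty(1 << G)
    for mask in range(1 << G):
        z = baseline.copy()
        for g in range(G):
            if mask >> g & 1:
                z[idx[g]] = x[idx[g]]
        values[mask] = float(score_fn(z))

    fact = [math.factorial(i) for i in range(G + 1)]
    phi = np.zeros(G)
    for g in range(G):
        for mask in range(1 << G):
            if mask >> g & 1:
                continue
            s = bin(mask).count("1")
            w = fact[s] * fact[G - s - 1] / fact[G]
            phi[g] += w * (values[mask | (1 << g)] - values[mask])
    return phi


def build_class_priors(model, samples, config: AttributionConfig,
                       background: Sequence[np.ndarray] | None = None) -> list[ClassPrior]:
    """Average per-sample attributions over correct predictions, per class.

    ``samples`` is a sequence of objects with ``volume`` and ``label``
    (e.g. ``synth.VolumeSample``). Correctness means
    ``argmax(predict_proba) == label`` with ties broken toward the lowest
    class index (numpy argmax). The background set defaults to a seeded
    subset of the cohort's NC volumes — the implicit reference condition —
    of size ``config.n_background``.

    Classes with no correct prediction yield an absent-prior marker; if no
    class has any correct prediction at all, that is a hard error.
    """
    samples = list(samples)
    if not samples:
        raise ValueError("empty sample set")
    K = model.config.n_classes
    volumes = np.stack([np.asarray(s.volume, dtype=np.float64) for s in samples])
    labels = np.array([s.label for s in samples])
    probs = model.predict_proba(volumes)
    preds = probs.argmax(axis=1)
    correct = preds == labels

    if background is None:
        nc = np.flatnonzero(labels == 0)
        if nc.size == 0:
            raise ValueError("no NC samples available for the background set; pass one explicitly")
        rng = np.random.default_rng(config.seed)
        pick = rng.choice(nc, size=min(config.n_background, nc.size), replace=False)
        background = [volumes[i] for i in sorted(pick)]

    priors: list[ClassPrior] = []
    any_correct = False
    for k in range(K):
        members = np.flatnonzero(correct & (labels == k))
        if members.size == 0:
            priors.append(ClassPrior(class_id=k, grid=None, n_samples_averaged=0))
            continue
        any_correct = True
        acc = np.zeros(volumes.shape[1:])
        for i in members:
            acc += attribute(model, volumes[i], k, background, config)
        priors.append(ClassPrior(class_id=k, grid=acc / members.size,
                                 n_samples_averaged=int(members.size)))
    if not any_correct:
        counts = np.bincount(labels, minlength=K)
        raise RuntimeError(
            "baseline model has no correct prediction for any class "
            f"(class counts {counts.tolist()}, predicted counts "
            f"{np.bincount(preds, minlength=K).tolist()}); priors cannot be built"
        )
    return priors


def scale_to_unit(prior: ClassPrior) -> ClassPrior:
    """Scale a raw prior into [-1, 1] by its maximum absolute value.

    Signs and zeros are preserved, so positive and negative voxel
    contributions keep their meaning. Intended for visualization; the
    similarity loss consumes raw priors. An all-zero grid is returned
    unchanged with a warning flag.
    """
    if prior.absent:
        raise ValueError("cannot scale an absent prior")
    m = float(np.abs(prior.grid).max())
    if m == 0.0:
        return ClassPrior(prior.class_id, prior.grid.copy(), prior.n_samples_averaged,
                          scale="unit", all_zero_warning=True)
    return ClassPrior(prior.class_id, prior.grid / m, prior.n_samples_averaged, scale="unit")


def resample_grid(grid: np.ndarray, target_shape: tuple[int, int, int]) -> np.ndarray:
    """Trilinear resampling with the align-corners convention.

    Target index i on an axis of length T maps to source coordinate
    ``i * (S - 1) / (T - 1)`` (or the axis midpoint when T == 1), so corner
    voxels map to corner voxels, constants stay constant, and linear ramps
    stay linear.
    """
    grid = np.asarray(grid, dtype=np.float64)
    if any(t < 1 for t in target_shape):
        raise ValueError("target_shape must be positive")
    if tuple(grid.shape) == tuple(target_shape):
        return grid.copy()
    axes = []
    for t, s in zip(target_shape, grid.shape):
        if t == 1:
            axes.append(np.full(1, (s - 1) / 2.0))
        else:
            axes.append(np.arange(t) * (s - 1) / (t - 1))
    coords = np.meshgrid(*axes, indexing="ij")
    return map_coordinates(grid, np.stack(coords), order=1, mode="nearest")


def resample_prior(prior: ClassPrior, target_shape: tuple[int, int, int]) -> ClassPrior:
    """Resample a prior grid to ``target_shape`` (e.g. attention resolution)."""
    if prior.absent:
        raise ValueError("cannot resample an absent prior")
    return ClassPrior(prior.class_id, resample_grid(prior.grid, target_shape),
                      prior.n_samples_averaged, scale=prior.scale,
                      all_zero_warning=prior.all_zero_warning)
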