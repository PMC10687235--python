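"""Differentiable toy scorers with closed-form gradients.

These stand in for a trained image classifier wherever the pipeline only
needs the :class:`~ihdrisk.saliency.Scorer` interface: a scalar score and
its exact pixel-wise derivative.  Each scorer accepts either a 2-D image
or a (C, H, W) channel stack and returns a gradient of the same shape.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class LinearScorer:
    """score(I) = Σ_ij W_ij · I_ij, so the gradient is W for every image.

    For a channel stack the same weights apply to each channel.
    """

    weights: np.ndarray

    def _broadcast(self, image: np.ndarray) -> np.ndarray:
        image = np.asarray(image, dtype=float)
        if image.ndim == 3:
            return np.broadcast_to(self.weights, image.shape)
        if image.shape != self.weights.shape:
            raise ValueError(f"image shape {image.shape} != weight shape {self.weights.shape}")
        return self.weights

    def score(self, image: np.ndarray) -> float:
        return float((self._broadcast(image) * np.asarray(image, dtype=float)).sum())

    def gradient(self, image: np.ndarray) -> np.ndarray:
        return np.array(self._broadcast(image), dtype=float)


def linear_scorer(weights: np.ndarray) -> LinearScorer:
    return LinearScorer(np.asarray(weights, dtype=float))


@dataclass(frozen=True)
class QuadraticScorer:
    """score(I) = Σ I², gradient 2I — a simple non-linear test scorer."""

    def score(self, image: np.ndarray) -> float:
        return float(np.square(np.asarray(image, dtype=float)).sum())

    def gradient(self, image: np.ndarray) -> np.ndarray:
        return 2.0 * np.asarray(image, dtype=float)


@dataclass(frozen=True)
class ConstantScorer:
    """score(I) = c; gradient identically zero (degenerate-saliency probe)."""

    value: float = 0.0

    def score(self, image: np.ndarray) -> float:
        return self.value

    def gradient(self, image: np.ndarray) -> np.ndarray:
        return np.zeros_like(np.asarray(image, dtype=float))


def class_weighted_scorer(mask: np.ndarray, cls: int, off_weight: float = 0.0) -> LinearScorer:
    """Linear scorer whose weight mass sits on one tissue class.

    Used to plant a known attribution signal: with ``off_weight`` 0 all
    saliency concentrates on ``cls`` pixels.
    """
    w = np.full(np.asarray(mask).shape, off_weight, dtype=float)
    w[np.asarray(mask) == cls] = 1.0
    return LinearScorer(w)


def check_gradient(
    scorer, image: np.ndarray, n_probes: int = 10, eps: float = 1e-4, seed: int = 0
) -> float:
    """Max relative error of the scorer gradient vs central finite differences.

    Probes ``n_probes`` random pixels; the Scorer contract requires the
    result to be small (1e-4 relative or better for smooth scorers).
    """
    rng = np.random.default_rng(seed)
    image = np.asarray(image, dtype=float)
    grad = np.asarray(scorer.gradient(image), dtype=float)
    flat_idx = rng.choice(image.size, size=min(n_probes, image.size), replace=False)
    worst = 0.0
    for idx in flat_idx:
        pos = np.unravel_index(idx, image.shape)
        bumped = image.copy()
        bumped[pos] += eps
        hi = scorer.score(bumped)
        bumped[pos] -= 2 * eps
        lo = scorer.score(bumped)
        fd = (hi - lo) / (2 * eps)
        scale = max(abs(fd), abs(grad[pos]), 1.0)
        worst = max(worst, abs(fd - grad[pos]) / scale)
    return worst
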