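"""Tissue saliency: gradient attribution aggregated by tissue class.

Given a differentiable risk scorer, the saliency map is the derivative
w_ij of the disease class score with respect to each input pixel.  For a
tissue class t the *observed* saliency

    S^O_t = Σ_{ij∈t} |w_ij| / Σ_{ij} |w_ij|

is the fraction of total L1 gradient magnitude falling in that class, and
the *expected* saliency

    S^E_t = |{ij : class(ij) = t}| / (total pixels)

is the class's pixel share.  At cohort level both are averaged per image
and summarised by the ratio of means O̅/E̅ per class, with a paired
two-tailed t-test on the per-image (S^O_t, S^E_t) pairs.  A ratio above 1
marks tissue drawing more model attention than its area alone predicts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Protocol, Sequence, runtime_checkable

import numpy as np
from scipy import stats

from .bodycomp import SALIENCY_CLASSES, Tissue
from .imaging import PreparedInput


@runtime_checkable
class Scorer(Protocol):
    """A differentiable risk scorer: a scalar score and its pixel gradient."""

    def score(self, image: np.ndarray) -> float: ...

    def gradient(self, image: np.ndarray) -> np.ndarray: ...


class UndefinedSaliencyError(ValueError):
    """Raised when total saliency is zero and fractions are undefined."""


def pixel_saliency(scorer: Scorer, image: np.ndarray | PreparedInput) -> np.ndarray:
    """Derivative of the class score with respect to each native pixel.

    Accepts either a raw 2-D image (the scorer's gradient is returned as-is,
    with 3-channel gradients summed over channels) or a
    :class:`~ihdrisk.imaging.PreparedInput`, in which case the gradient is
    computed on the resized grid and pulled back to native pixel coordinates
    through the resize adjoint.
    """
    if isinstance(image, PreparedInput):
        grad = np.asarray(scorer.gradient(image.channels), dtype=float)
        w = image.pull_back(grad)
    else:
        grad = np.asarray(scorer.gradient(np.asarray(image)), dtype=float)
        w = grad.sum(axis=0) if grad.ndim == 3 else grad
    if not np.isfinite(w).all():
        raise ValueError("scorer returned a non-finite gradient")
    return w


def observed_saliency(
    sal: np.ndarray, mask: np.ndarray, classes: Sequence[int] = SALIENCY_CLASSES
) -> dict[int, float]:
    """Fraction of total |w| in each tissue class; fractions sum to 1."""
    sal = np.asarray(sal, dtype=float)
    mask = np.asarray(mask)
    if sal.shape != mask.shape:
        raise ValueError(f"shape mismatch: {sal.shape} vs {mask.shape}")
    mag = np.abs(sal)
    peak = mag.max()
    if peak == 0:
        raise UndefinedSaliencyError("total saliency is zero; observed fractions undefined")
    mag = mag / peak  # scale-free; constant maps become exact integer counts
    total = mag.sum()
    return {int(c): float(mag[mask == c].sum() / total) for c in classes}


def expected_saliency(
    mask: np.ndarray, classes: Sequence[int] = SALIENCY_CLASSES
) -> dict[int, float]:
    """Pixel share of each tissue class; shares sum to 1."""
    mask = np.asarray(mask)
    n = mask.size
    return {int(c): float((mask == c).sum() / n) for c in classes}


def assign_saliency_classes(mask: np.ndarray, body: np.ndarray) -> np.ndarray:
    """Resolve a segmentation against a body mask into the five classes.

    Inside the body, pixels not labelled muscle/VAT/SAT (including BONE)
    become OTHER; every pixel outside the body becomes BACKGROUND — the body
    mask wins, so a stray "muscle" label outside the body is background.
    """
    mask = np.asarray(mask)
    body = np.asarray(body, dtype=bool)
    if mask.shape != body.shape:
        raise ValueError(f"shape mismatch: {mask.shape} vs {body.shape}")
    out = np.full(mask.shape, int(Tissue.OTHER), dtype=np.uint8)
    for cls in (Tissue.MUSCLE, Tissue.VAT, Tissue.SAT):
        out[mask == cls] = cls
    out[~body] = Tissue.BACKGROUND
    return out


@dataclass(frozen=True)
class TissueSaliencyResult:
    """Per-image observed and expected saliency fractions by class."""

    observed: dict[int, float]
    expected: dict[int, float]


def image_saliency(
    scorer: Scorer, image: np.ndarray | PreparedInput, mask: np.ndarray
) -> TissueSaliencyResult:
    """Full per-image pipeline: gradient, then observed/expected fractions."""
    w = pixel_saliency(scorer, image)
    return TissueSaliencyResult(observed_saliency(w, mask), expected_saliency(mask))


@dataclass(frozen=True)
class CohortSaliency:
    """Cohort aggregate: per class the mean observed fraction O̅, mean
    expected fraction E̅, their ratio O̅/E̅ and a paired t-test p-value."""

    mean_observed: dict[int, float]
    mean_expected: dict[int, float]
    ratio: dict[int, float]
    p_value: dict[int, float]
    n_images: int
    n_excluded: int = 0

    def ranked_classes(self) -> list[int]:
        """Classes ordered by descending observed/expected ratio."""
        return sorted(self.ratio, key=self.ratio.get, reverse=True)


def cohort_saliency(
    results: Sequence[TissueSaliencyResult],
    classes: Sequence[int] = SALIENCY_CLASSES,
    n_excluded: int = 0,
) -> CohortSaliency:
    """Aggregate per-image saliency into cohort O̅/E̅ ratios and t-tests.

    The headline statistic is the ratio of cohort means (not the mean of
    per-image ratios).  With fewer than two images the ratios are still
    computed but p-values are undefined (NaN, with a warning).
    """
    if not results:
        raise ValueError("need at least one image result")
    n = len(results)
    obs = {int(c): np.array([r.observed[int(c)] for r in results]) for c in classes}
    exp = {int(c): np.array([r.expected[int(c)] for r in results]) for c in classes}
    mean_obs = {c: float(v.mean()) for c, v in obs.items()}
    mean_exp = {c: float(v.mean()) for c, v in exp.items()}
    ratio = {
        c: (mean_obs[c] / mean_exp[c]) if mean_exp[c] > 0 else float("nan") for c in mean_obs
    }
    pvals: dict[int, float] = {}
    if n < 2:
        warnings.warn("fewer than 2 images: paired t-test p-values undefined", stacklevel=2)
        pvals = {c: float("nan") for c in mean_obs}
    else:
        for c in mean_obs:
            diff = obs[c] - exp[c]
            if np.allclose(diff, diff[0]):
                # zero-variance pairs: identical S^O and S^E give p = 1
                pvals[c] = 1.0 if np.allclose(diff, 0.0) else 0.0
            else:
                pvals[c] = float(stats.ttest_rel(obs[c], exp[c]).pvalue)
    return CohortSaliency(mean_obs, mean_exp, ratio, pvals, n_images=n, n_excluded=n_excluded)


def run_cohort(
    scorer: Scorer,
    images: Sequence[np.ndarray | PreparedInput],
    masks: Sequence[np.ndarray],
) -> CohortSaliency:
    """Score a cohort image-by-image and aggregate.

    Images whose total saliency is zero carry no attribution signal; they
    are excluded from the averages and counted in ``n_excluded``.
    """
    if len(images) != len(masks):
        raise ValueError("images and masks must pair up")
    results = []
    excluded = 0
    for img, msk in zip(images, masks):
        try:
            results.append(image_saliency(scorer, img, msk))
        except UndefinedSaliencyError:
            excluded += 1
    if excluded:
        warnings.warn(f"excluded {excluded} zero-saliency image(s) from cohort averages",
                      stacklevel=2)
    return cohort_saliency(results, n_excluded=excluded)
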