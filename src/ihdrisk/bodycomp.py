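"""Body-composition metrics, segmentation evaluation, and a reference
attenuation-threshold segmenter.

Tissue masks are 2-D ``uint8`` arrays with labels from :class:`Tissue`.
The five saliency classes are BACKGROUND, MUSCLE, VAT (visceral adipose
tissue), SAT (subcutaneous adipose tissue) and OTHER; BONE is an extended
label used by manual annotations and collapses to OTHER for saliency.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np
from scipy import ndimage


class Tissue(IntEnum):
    BACKGROUND = 0
    MUSCLE = 1
    VAT = 2
    SAT = 3
    OTHER = 4
    BONE = 5


#: The five classes over which tissue saliency is partitioned.
SALIENCY_CLASSES = (
    Tissue.BACKGROUND,
    Tissue.MUSCLE,
    Tissue.VAT,
    Tissue.SAT,
    Tissue.OTHER,
)

# Attenuation ranges (HU) conventionally used for L3 body composition.
ADIPOSE_HU_RANGE = (-190.0, -30.0)
MUSCLE_HU_RANGE = (-29.0, 150.0)


@dataclass(frozen=True)
class BodyCompFeatures:
    """The two body-composition biomarkers used for risk modelling."""

    mean_muscle_hu: float
    vat_area_cm2: float
    sat_area_cm2: float
    vat_sat_ratio: float


def _check_shapes(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")


def dice(a: np.ndarray, b: np.ndarray, cls: int) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|) for one tissue class.

    Symmetric in its mask arguments.  When the class is absent from both
    masks the score is defined as 1.0 (perfect agreement on absence).
    """
    a = np.asarray(a)
    b = np.asarray(b)
    _check_shapes(a, b)
    ma = a == cls
    mb = b == cls
    denom = int(ma.sum()) + int(mb.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((ma & mb).sum()) / denom


def rms_cv(pairs: list[tuple[float, float]]) -> float:
    """Root-mean-square coefficient of variation between paired measurements.

    Each (manual, automated) pair contributes CV_i = (|m−a|/√2)/mean(m,a),
    the duplicate-measurement convention (the s.d. of a pair is |d|/√2).
    Returns 100·sqrt(mean CV_i²), in percent.
    """
    if not pairs:
        raise ValueError("need at least one measurement pair")
    cvs = []
    for m, a in pairs:
        mean = (m + a) / 2.0
        if mean <= 0:
            raise ValueError(f"pair mean must be positive, got {(m, a)}")
        cvs.append((abs(m - a) / np.sqrt(2.0)) / mean)
    return 100.0 * float(np.sqrt(np.mean(np.square(cvs))))


def tissue_area(mask: np.ndarray, cls: int, spacing_mm: tuple[float, float]) -> float:
    """Cross-sectional area of a class in cm²: pixel count × pixel area."""
    count = int((np.asarray(mask) == cls).sum())
    return count * spacing_mm[0] * spacing_mm[1] / 100.0


def mean_radiodensity(pixels: np.ndarray, mask: np.ndarray, cls: int) -> float:
    """Mean HU over the pixels of one class; empty classes are an error."""
    pixels = np.asarray(pixels)
    mask = np.asarray(mask)
    _check_shapes(pixels, mask)
    sel = mask == cls
    if not sel.any():
        raise ValueError(f"class {Tissue(cls).name} is empty; mean radiodensity undefined")
    return float(pixels[sel].mean())


def vat_sat_ratio(mask: np.ndarray) -> float:
    """VAT/SAT cross-sectional area ratio (pixel spacing cancels)."""
    mask = np.asarray(mask)
    n_sat = int((mask == Tissue.SAT).sum())
    if n_sat == 0:
        raise ValueError("SAT area is zero; VAT/SAT ratio undefined")
    return int((mask == Tissue.VAT).sum()) / n_sat


def extract_features(
    pixels: np.ndarray, mask: np.ndarray, spacing_mm: tuple[float, float]
) -> BodyCompFeatures:
    """Mean muscle radiodensity plus VAT/SAT areas and their ratio."""
    return BodyCompFeatures(
        mean_muscle_hu=mean_radiodensity(pixels, mask, Tissue.MUSCLE),
        vat_area_cm2=tissue_area(mask, Tissue.VAT, spacing_mm),
        sat_area_cm2=tissue_area(mask, Tissue.SAT, spacing_mm),
        vat_sat_ratio=vat_sat_ratio(mask),
    )


def threshold_segmenter(
    pixels: np.ndarray,
    body: np.ndarray,
    adipose_hu: tuple[float, float] = ADIPOSE_HU_RANGE,
    muscle_hu: tuple[float, float] = MUSCLE_HU_RANGE,
) -> np.ndarray:
    """Reference attenuation-threshold segmentation inside a body mask.

    A stand-in for a trained segmentation network, echoing the manual
    protocol of thresholding plus anatomical rules:

    * adipose = HU in ``adipose_hu`` within the body;
    * SAT = adipose components adjacent to the body surface, other adipose
      components are VAT;
    * muscle = pixels in ``muscle_hu`` belonging to components adjacent to
      SAT (the abdominal-wall annulus); interior soft tissue in the same HU
      range stays OTHER;
    * everything else in the body is OTHER; outside the body, BACKGROUND.
    """
    pixels = np.asarray(pixels)
    body = np.asarray(body, dtype=bool)
    _check_shapes(pixels, body)
    if not body.any():
        raise ValueError("empty body mask")

    out = np.full(pixels.shape, int(Tissue.BACKGROUND), dtype=np.uint8)
    out[body] = Tissue.OTHER

    adipose = body & (pixels >= adipose_hu[0]) & (pixels <= adipose_hu[1])
    surface = body & ~ndimage.binary_erosion(body, iterations=2)
    ad_labels, n_ad = ndimage.label(adipose)
    sat = np.zeros_like(adipose)
    vat = np.zeros_like(adipose)
    for comp in range(1, n_ad + 1):
        sel = ad_labels == comp
        if (sel & surface).any():
            sat |= sel
        else:
            vat |= sel

    muscle_cand = body & (pixels >= muscle_hu[0]) & (pixels <= muscle_hu[1])
    muscle = np.zeros_like(muscle_cand)
    if sat.any() and muscle_cand.any():
        near_sat = ndimage.binary_dilation(sat)
        mu_labels, n_mu = ndimage.label(muscle_cand)
        for comp in range(1, n_mu + 1):
            sel = mu_labels == comp
            if (sel & near_sat).any():
                muscle |= sel

    out[sat] = Tissue.SAT
    out[vat] = Tissue.VAT
    out[muscle] = Tissue.MUSCLE
    return out
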