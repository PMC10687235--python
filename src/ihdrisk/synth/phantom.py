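"""Synthetic L3-level CT phantoms with ground-truth tissue masks.

The phantom emulates the anatomy segmented at the third lumbar vertebra
as concentric ellipses: a subcutaneous-fat (SAT) ring just under the
skin, a muscle wall beneath it, and an inner cavity holding visceral fat
(VAT) around a central block of other tissue (viscera).  Air background
sits at about -1000 HU and an optional thin scanner-bed strip of ~0 HU
lies below the body.  Geometry is specified in millimetres so pixel
spacing enters area computations the same way it does for real CT.

Chosen for closed-form areas: every class region is an ellipse
difference, so expected pixel fractions are analytic and discretisation
is the only error.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ..bodycomp import Tissue, extract_features
from ..imaging import CTSlice

#: Per-class (mean, sd) HU defaults, within published attenuation conventions.
DEFAULT_HU_PARAMS: dict[Tissue, tuple[float, float]] = {
    Tissue.BACKGROUND: (-1000.0, 5.0),
    Tissue.SAT: (-100.0, 15.0),
    Tissue.VAT: (-90.0, 15.0),
    Tissue.MUSCLE: (45.0, 12.0),
    Tissue.OTHER: (30.0, 40.0),
}


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and attenuation parameters of a single phantom."""

    image_size: int = 256
    pixel_spacing_mm: tuple[float, float] = (1.5, 1.5)
    body_axes_mm: tuple[float, float] = (150.0, 105.0)  # (col semi-axis, row semi-axis)
    sat_thickness_mm: float = 18.0
    muscle_wall_mm: float = 12.0
    vat_fraction: float = 0.35
    hu_params: dict[Tissue, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_HU_PARAMS)
    )
    bed_present: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size < 64:
            raise ValueError("image_size must be >= 64")
        if min(self.pixel_spacing_mm) <= 0:
            raise ValueError("pixel spacing must be positive")
        a, b = self.body_axes_mm
        if a <= 0 or b <= 0:
            raise ValueError("body semi-axes must be positive")
        if self.sat_thickness_mm <= 0 or self.muscle_wall_mm <= 0:
            raise ValueError("tissue layer widths must be positive")
        if self.sat_thickness_mm + self.muscle_wall_mm >= min(a, b):
            raise ValueError("SAT + muscle widths must leave a non-empty inner cavity")
        if not 0.0 < self.vat_fraction < 1.0:
            raise ValueError("vat_fraction must lie strictly in (0, 1)")
        for cls, (_, sd) in self.hu_params.items():
            if sd < 0:
                raise ValueError(f"negative HU sd for {Tissue(cls).name}")
        fat_means = (self.hu_params[Tissue.SAT][0], self.hu_params[Tissue.VAT][0])
        if not all(m < self.hu_params[Tissue.MUSCLE][0] for m in fat_means):
            raise ValueError("fat HU means must be below the muscle HU mean")

    @property
    def cavity_axes_mm(self) -> tuple[float, float]:
        shrink = self.sat_thickness_mm + self.muscle_wall_mm
        return (self.body_axes_mm[0] - shrink, self.body_axes_mm[1] - shrink)


def _inside(xx: np.ndarray, yy: np.ndarray, a: float, b: float) -> np.ndarray:
    return (xx / a) ** 2 + (yy / b) ** 2 <= 1.0


def rasterize_mask(spec: PhantomSpec) -> np.ndarray:
    """Ground-truth label grid for the phantom geometry (no HU noise)."""
    n = spec.image_size
    sr, sc = spec.pixel_spacing_mm
    rows = (np.arange(n) - (n - 1) / 2.0) * sr
    cols = (np.arange(n) - (n - 1) / 2.0) * sc
    yy, xx = np.meshgrid(rows, cols, indexing="ij")

    a, b = spec.body_axes_mm
    t_sat, t_mus = spec.sat_thickness_mm, spec.muscle_wall_mm
    cav_a, cav_b = spec.cavity_axes_mm
    oth_scale = np.sqrt(1.0 - spec.vat_fraction)

    body = _inside(xx, yy, a, b)
    inner_sat = _inside(xx, yy, a - t_sat, b - t_sat)
    cavity = _inside(xx, yy, cav_a, cav_b)
    other = _inside(xx, yy, cav_a * oth_scale, cav_b * oth_scale)

    mask = np.full((n, n), int(Tissue.BACKGROUND), dtype=np.uint8)
    mask[body & ~inner_sat] = Tissue.SAT
    mask[inner_sat & ~cavity] = Tissue.MUSCLE
    mask[cavity & ~other] = Tissue.VAT
    mask[other] = Tissue.OTHER

    for cls in (Tissue.SAT, Tissue.MUSCLE, Tissue.VAT, Tissue.OTHER):
        if not (mask == cls).any():
            raise ValueError(f"phantom geometry leaves class {cls.name} empty")
    if not (mask == Tissue.BACKGROUND).any():
        raise ValueError("phantom geometry leaves class BACKGROUND empty")
    return mask


def analytic_class_fractions(spec: PhantomSpec) -> dict[Tissue, float]:
    """Closed-form expected pixel fraction of each class (ellipse areas)."""
    n = spec.image_size
    sr, sc = spec.pixel_spacing_mm
    image_area = (n * sr) * (n * sc)
    a, b = spec.body_axes_mm
    shrink = spec.sat_thickness_mm
    area = {
        "body": np.pi * a * b,
        "inner_sat": np.pi * (a - shrink) * (b - shrink),
        "cavity": np.pi * spec.cavity_axes_mm[0] * spec.cavity_axes_mm[1],
    }
    area["other"] = area["cavity"] * (1.0 - spec.vat_fraction)
    fr = {
        Tissue.SAT: (area["body"] - area["inner_sat"]) / image_area,
        Tissue.MUSCLE: (area["inner_sat"] - area["cavity"]) / image_area,
        Tissue.VAT: (area["cavity"] - area["other"]) / image_area,
        Tissue.OTHER: area["other"] / image_area,
    }
    fr[Tissue.BACKGROUND] = 1.0 - sum(fr.values())
    return fr


def make_phantom(spec: PhantomSpec) -> tuple[CTSlice, np.ndarray]:
    """Render a phantom slice and its ground-truth mask, deterministically.

    HU values in each class are drawn from that class's Normal(mean, sd),
    clipped to the representable CT range.  The scanner bed, when present,
    is a thin ~0 HU strip touching the bottom image edge; it belongs to the
    BACKGROUND class in the mask.
    """
    mask = rasterize_mask(spec)
    rng = np.random.default_rng(spec.seed)
    n = spec.image_size
    pixels = np.empty((n, n), dtype=float)
    for cls in (Tissue.BACKGROUND, Tissue.SAT, Tissue.MUSCLE, Tissue.VAT, Tissue.OTHER):
        sel = mask == cls
        mean, sd = spec.hu_params[cls]
        pixels[sel] = rng.normal(mean, sd, size=int(sel.sum()))
    if spec.bed_present:
        bed = np.zeros((n, n), dtype=bool)
        bed[n - 5 :, n // 8 : n - n // 8] = True
        bed &= mask == Tissue.BACKGROUND
        pixels[bed] = rng.normal(0.0, 15.0, size=int(bed.sum()))
    pixels = np.clip(pixels, -1024, 3071)
    return CTSlice(pixels, spec.pixel_spacing_mm), mask


#: Feature names an imaging outcome model may reference.
IMAGING_FEATURES = ("mean_muscle_hu", "vat_sat_ratio")


@dataclass
class ImagingCohort:
    """A synthetic imaging cohort with known outcome model."""

    slices: list[CTSlice]
    masks: list[np.ndarray]
    labels: np.ndarray
    features: pd.DataFrame
    true_linear_predictor: np.ndarray
    coefficients: dict[str, float]


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Size, prevalence and planted logistic outcome model of a cohort."""

    n_patients: int
    prevalence_target: float = 0.25
    outcome_coefficients: dict[str, float] = field(default_factory=dict)
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        if not 0.0 < self.prevalence_target < 1.0:
            raise ValueError("prevalence_target must lie in (0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _solve_intercept(lp: np.ndarray, target: float) -> float:
    """Intercept making mean sigmoid(lp + c) equal the target prevalence."""
    from scipy.optimize import brentq

    def gap(c: float) -> float:
        return float(np.mean(1.0 / (1.0 + np.exp(-(lp + c))))) - target

    return float(brentq(gap, -30.0, 30.0))


def make_imaging_cohort(
    spec: SyntheticCohortSpec, phantom: PhantomSpec | None = None
) -> ImagingCohort:
    """Generate phantoms with per-patient jitter and logistic outcome labels.

    Coefficients act on z-scored body-composition features; an intercept is
    solved so the expected prevalence matches ``prevalence_target``.  The
    label RNG stream is separate from the geometry/HU stream so outcomes and
    imaging noise are independent draws.
    """
    phantom = phantom or PhantomSpec()
    unknown = set(spec.outcome_coefficients) - set(IMAGING_FEATURES)
    if unknown:
        raise ValueError(f"outcome coefficients reference unknown features: {sorted(unknown)}")

    geom_rng = np.random.default_rng([spec.seed, 0])
    label_rng = np.random.default_rng([spec.seed, 1])

    slices, masks, rows = [], [], []
    for i in range(spec.n_patients):
        scale_a = float(np.clip(geom_rng.normal(1.0, 0.06), 0.85, 1.15))
        scale_b = float(np.clip(geom_rng.normal(1.0, 0.06), 0.85, 1.15))
        vf = float(np.clip(geom_rng.normal(phantom.vat_fraction, 0.08), 0.10, 0.70))
        hu = dict(phantom.hu_params)
        mu_mean, mu_sd = hu[Tissue.MUSCLE]
        hu[Tissue.MUSCLE] = (mu_mean + float(geom_rng.normal(0.0, 6.0)), mu_sd)
        p = replace(
            phantom,
            body_axes_mm=(phantom.body_axes_mm[0] * scale_a, phantom.body_axes_mm[1] * scale_b),
            sat_thickness_mm=phantom.sat_thickness_mm * float(geom_rng.uniform(0.7, 1.3)),
            vat_fraction=vf,
            hu_params=hu,
            seed=int(geom_rng.integers(0, 2**31 - 1)),
        )
        slc, mask = make_phantom(p)
        slices.append(slc)
        masks.append(mask)
        feats = extract_features(slc.pixels, mask, slc.pixel_spacing_mm)
        rows.append({"mean_muscle_hu": feats.mean_muscle_hu, "vat_sat_ratio": feats.vat_sat_ratio})

    features = pd.DataFrame(rows)
    z = (features - features.mean()) / features.std(ddof=0).replace(0.0, 1.0)
    lp = np.zeros(spec.n_patients)
    for name, beta in spec.outcome_coefficients.items():
        lp += beta * z[name].to_numpy()
    # noise perturbs the label draw only; the retained oracle predictor is β·z
    noisy = lp + label_rng.normal(0.0, spec.noise_sd, size=spec.n_patients) if spec.noise_sd > 0 else lp
    intercept = _solve_intercept(noisy, spec.prevalence_target)
    prob = 1.0 / (1.0 + np.exp(-(noisy + intercept)))
    labels = (label_rng.uniform(size=spec.n_patients) < prob).astype(int)
    return ImagingCohort(slices, masks, labels, features, lp, dict(spec.outcome_coefficients))
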