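"""CT slice containers and deterministic preprocessing.

Hounsfield-unit (HU) conventions: air is about -1000 HU, water 0 HU,
skeletal muscle roughly 40-50 HU.  All operations here are pure and
shape-preserving unless documented otherwise; images and masks are
row-major 2-D numpy arrays with 0-based indices and pixel-centre
coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

HU_MIN = -1024
HU_MAX = 3071

#: Standard window presets (width, level) used for 3-channel stacking:
#: soft tissue 400/50, bone 1800/400, and a wider custom soft window 500/50.
WINDOW_PRESETS: dict[str, tuple[float, float]] = {
    "soft": (400.0, 50.0),
    "bone": (1800.0, 400.0),
    "custom": (500.0, 50.0),
}


@dataclass(frozen=True)
class WindowSpec:
    """A display window: ``width`` HU shown, centred on ``level`` HU."""

    width: float
    level: float

    def __post_init__(self) -> None:
        if not self.width > 0:
            raise ValueError(f"window width must be > 0, got {self.width}")


@dataclass
class CTSlice:
    """A single axial CT slice in Hounsfield units.

    Parameters
    ----------
    pixels
        2-D array of HU values, clipped on construction to the scanner
        range [-1024, 3071].
    pixel_spacing_mm
        (row, col) physical pixel size in millimetres; both > 0.
    """

    pixels: np.ndarray
    pixel_spacing_mm: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("pixels must be a non-empty 2-D array")
        if not all(s > 0 for s in self.pixel_spacing_mm):
            raise ValueError(f"pixel spacing must be positive, got {self.pixel_spacing_mm}")
        if px.min() < HU_MIN or px.max() > HU_MAX:
            raise ValueError("HU values outside the representable range [-1024, 3071]")
        self.pixels = px

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def pixel_area_cm2(self) -> float:
        r, c = self.pixel_spacing_mm
        return r * c / 100.0


def clip_hu(slc: CTSlice, lo: float = -1000.0, hi: float = 1000.0) -> CTSlice:
    """Clamp every pixel to [lo, hi]; shape and spacing are preserved."""
    if lo >= hi:
        raise ValueError(f"require lo < hi, got ({lo}, {hi})")
    return CTSlice(np.clip(slc.pixels, lo, hi), slc.pixel_spacing_mm)


def apply_window(slc: CTSlice, window: WindowSpec) -> np.ndarray:
    """Map HU to [0, 1] through a linear window/level ramp.

    v -> clamp((v - (level - width/2)) / width, 0, 1): pixels at the window
    centre map to 0.5 and the ramp saturates half a width either side.
    """
    lo = window.level - window.width / 2.0
    return np.clip((slc.pixels.astype(float) - lo) / window.width, 0.0, 1.0)


def stack_channels(slc: CTSlice, windows: list[WindowSpec] | None = None) -> np.ndarray:
    """Stack the slice under three window settings into a (3, H, W) array.

    Defaults to the soft/bone/custom presets used for segmentation input.
    """
    if windows is None:
        windows = [WindowSpec(*WINDOW_PRESETS[k]) for k in ("soft", "bone", "custom")]
    if len(windows) != 3:
        raise ValueError(f"expected exactly 3 windows, got {len(windows)}")
    return np.stack([apply_window(slc, w) for w in windows])


def _interp_matrix(n_in: int, n_out: int) -> np.ndarray:
    """Dense 1-D linear-interpolation operator (n_out, n_in), corner-aligned.

    Output sample i reads input coordinate i*(n_in-1)/(n_out-1), so the first
    and last samples coincide with the input endpoints and constants are
    reproduced exactly.  Separable 2-D resize is R @ img @ C.T and its adjoint
    (used to pull gradients back to the native grid) is R.T @ g @ C.
    """
    if n_out == 1:
        out = np.zeros((1, n_in))
        out[0, 0] = 1.0
        return out
    src = np.arange(n_out) * (n_in - 1) / (n_out - 1)
    lo = np.minimum(np.floor(src).astype(int), n_in - 2) if n_in > 1 else np.zeros(n_out, int)
    frac = src - lo
    mat = np.zeros((n_out, n_in))
    mat[np.arange(n_out), lo] = 1.0 - frac
    if n_in > 1:
        mat[np.arange(n_out), lo + 1] += frac
    return mat


@dataclass
class PreparedInput:
    """A scorer-ready image plus the linear maps needed to pull gradients back.

    ``channels`` is the (3, out, out) clipped/replicated/resized image; the
    row/col operators record the bilinear resize so that saliency computed on
    the resized grid can be mapped (by the resize adjoint) onto native pixels.
    """

    channels: np.ndarray
    native_shape: tuple[int, int]
    row_op: np.ndarray = field(repr=False)
    col_op: np.ndarray = field(repr=False)

    def pull_back(self, grad: np.ndarray) -> np.ndarray:
        """Map a gradient on the prepared image back to native pixels.

        Channel gradients are summed first (the three channels are copies of
        one underlying image), then pushed through the resize adjoint.
        """
        g = np.asarray(grad, dtype=float)
        if g.ndim == 3:
            g = g.sum(axis=0)
        if g.shape != self.channels.shape[1:]:
            raise ValueError(f"gradient shape {g.shape} does not match prepared shape")
        return self.row_op.T @ g @ self.col_op


def prepare_scorer_input(slc: CTSlice, out_size: int | None = None) -> PreparedInput:
    """Clip to [-1000, 1000] HU, replicate to 3 channels and bilinearly resize.

    Mirrors the contract of feeding a grayscale L3 slice to an image
    classifier: a HxW slice becomes 3 x out_size x out_size.  With
    ``out_size`` equal to the input size the resize is the identity.
    """
    h, w = slc.shape
    if out_size is None:
        out_size = h
    if out_size < 8:
        raise ValueError(f"out_size must be >= 8, got {out_size}")
    clipped = np.clip(slc.pixels.astype(float), -1000.0, 1000.0)
    row_op = _interp_matrix(h, out_size)
    col_op = _interp_matrix(w, out_size)
    resized = row_op @ clipped @ col_op.T
    return PreparedInput(
        channels=np.repeat(resized[None], 3, axis=0),
        native_shape=(h, w),
        row_op=row_op,
        col_op=col_op,
    )


class EmptyBodyMaskError(ValueError):
    """Raised when no body-like component exists in a slice."""


def extract_body_mask(
    slc: CTSlice,
    air_threshold_hu: float = -200.0,
    bed_area_fraction: float = 0.2,
) -> np.ndarray:
    """Segment the patient's body, discarding background and the scanner bed.

    Pixels above ``air_threshold_hu`` are candidate tissue; connected
    components whose bounding box touches the bottom image edge and whose
    area is below ``bed_area_fraction`` of the largest component are treated
    as the CT bed and removed; the largest remaining component is kept and
    its internal holes filled.

    Returns a boolean mask aligned with the slice.  Raises
    :class:`EmptyBodyMaskError` for an all-air slice.
    """
    fore = slc.pixels > air_threshold_hu
    labels, n = ndimage.label(fore)
    if n == 0:
        raise EmptyBodyMaskError("no pixels above the air threshold; slice contains no body")
    areas = ndimage.sum_labels(fore, labels, index=np.arange(1, n + 1))
    largest_area = areas.max()
    bottom_row = slc.shape[0] - 1
    keep = []
    for comp in range(1, n + 1):
        touches_bottom = bool((labels[bottom_row] == comp).any())
        if touches_bottom and areas[comp - 1] < bed_area_fraction * largest_area:
            continue  # bed-like strip
        keep.append(comp)
    if not keep:
        raise EmptyBodyMaskError("all components rejected as bed-like")
    keep_areas = {c: areas[c - 1] for c in keep}
    body_comp = max(keep_areas, key=keep_areas.get)
    mask = labels == body_comp
    return ndimage.binary_fill_holes(mask)
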