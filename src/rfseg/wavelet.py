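"""Undecimated separable 2-D dyadic wavelet decomposition (a-trous scheme).

Every subband keeps the input's shape: instead of subsampling after each
level, the analysis filters are upsampled by inserting ``2**(j-1) - 1`` zeros
between taps at level ``j``.  The overcomplete representation is
shift-covariant (with periodic extension, exactly so), which is the point of
using it for per-pixel texture features.  Decomposing to level ``l`` yields
``d = 3l + 1`` subbands: the final approximation LL_l plus horizontal,
vertical and diagonal details (LH, HL, HH) of every level.

Filter-bank conventions
-----------------------
* The 6-tap Daubechies orthonormal pair is the default; the highpass is the
  quadrature mirror of the lowpass, ``h_hi[k] = (-1)**k * h_lo[5-k]``.
* The sqrt(2) (two-scale) normalization is kept at every level.  Any fixed
  scalar convention only rescales features; since the downstream clustering
  is scale-sensitive per feature, the convention is fixed and documented.
* Filtering is correlation with the forward filters, i.e. convolution with
  the time-reversed filters, applied to rows then columns.
* Boundary handling: symmetric (mirror) by default; periodic selectable.
* Subband naming: the first letter is the filter along rows (x), the second
  along columns (y); LH responds to horizontal structure, HL to vertical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from scipy.ndimage import correlate1d

__all__ = [
    "FilterPair",
    "DecompositionStack",
    "FeatureMatrix",
    "db6_filters",
    "undecimated_decompose",
    "masked_feature_matrix",
    "min_image_size",
]

_MODE_MAP = {"symmetric": "reflect", "periodic": "wrap"}


@dataclass(frozen=True)
class FilterPair:
    """Analysis lowpass/highpass pair of a two-channel filter bank."""

    lowpass: np.ndarray
    highpass: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "lowpass", np.asarray(self.lowpass, float))
        object.__setattr__(self, "highpass", np.asarray(self.highpass, float))
        if self.lowpass.ndim != 1 or self.highpass.ndim != 1:
            raise ValueError("filters must be 1-D")
        if self.lowpass.shape != self.highpass.shape:
            raise ValueError("lowpass and highpass must have equal length")


@dataclass
class DecompositionStack:
    """Ordered same-shape subbands of an undecimated decomposition.

    ``subbands[0]`` is LL_l; then LH_1, HL_1, HH_1, ..., LH_l, HL_l, HH_l.
    """

    subbands: list[np.ndarray]
    names: list[str]
    level: int

    @property
    def d(self) -> int:
        return len(self.subbands)

    def as_array(self) -> np.ndarray:
        """Stack as a (d, M, N) array."""
        return np.stack(self.subbands)


@dataclass
class FeatureMatrix:
    """Per-pixel feature vectors of the masked region, in raster order."""

    values: np.ndarray  # (n, d)
    pixel_index: np.ndarray  # (n, 2) of (row, col)
    feature_names: list[str]

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]


def db6_filters() -> FilterPair:
    """Orthonormal Daubechies 6-tap analysis filter pair.

    The lowpass sums to sqrt(2) and has unit squared norm; the highpass is
    its quadrature mirror and sums to zero.
    """
    lo = np.asarray(pywt.Wavelet("db3").dec_lo, float)
    k = np.arange(lo.size)
    hi = (-1.0) ** k * lo[::-1]
    return FilterPair(lo, hi)


def _upsampled(taps: np.ndarray, level: int) -> np.ndarray:
    """Insert ``2**(level-1) - 1`` zeros between taps (a-trous dilation)."""
    step = 2 ** (level - 1)
    if step == 1:
        return taps
    out = np.zeros((taps.size - 1) * step + 1)
    out[::step] = taps
    return out


def min_image_size(level: int, filter_length: int = 6) -> int:
    """Smallest image side supported at ``level`` (dilated filter support)."""
    return (filter_length - 1) * 2 ** (level - 1) + 1


def undecimated_decompose(
    image: np.ndarray,
    level: int,
    filters: FilterPair | None = None,
    mode: str = "symmetric",
) -> DecompositionStack:
    """Decompose an image to ``level`` without downsampling.

    Parameters
    ----------
    image : 2-D array
    level : int
        Number of dyadic scales (>= 1); yields ``3*level + 1`` subbands.
    filters : FilterPair, optional
        Analysis pair; defaults to the Daubechies 6-tap pair.
    mode : {"symmetric", "periodic"}
        Boundary extension.  Symmetric avoids edge artifacts at the skull
        boundary; periodic makes the transform exactly shift-covariant.
    """
    image = np.asarray(image, float)
    if image.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {image.shape}")
    if level < 1:
        raise ValueError(f"level must be >= 1, got {level}")
    if mode not in _MODE_MAP:
        raise ValueError(f"mode must be one of {sorted(_MODE_MAP)}, got {mode!r}")
    if filters is None:
        filters = db6_filters()
    need = min_image_size(level, filters.lowpass.size)
    if min(image.shape) < need:
        raise ValueError(
            f"image of shape {image.shape} too small for level {level}; "
            f"each side must be >= {need}"
        )
    nd_mode = _MODE_MAP[mode]

    approx = image
    details: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []
    for j in range(1, level + 1):
        lo = _upsampled(filters.lowpass, j)
        hi = _upsampled(filters.highpass, j)
        # rows = axis 1 (x direction), then columns = axis 0 (y direction)
        row_lo = correlate1d(approx, lo, axis=1, mode=nd_mode)
        row_hi = correlate1d(approx, hi, axis=1, mode=nd_mode)
        ll = correlate1d(row_lo, lo, axis=0, mode=nd_mode)
        lh = correlate1d(row_lo, hi, axis=0, mode=nd_mode)
        hl = correlate1d(row_hi, lo, axis=0, mode=nd_mode)
        hh = correlate1d(row_hi, hi, axis=0, mode=nd_mode)
        details.append((lh, hl, hh))
        approx = ll

    subbands = [approx]
    names = [f"LL{level}"]
    for j, (lh, hl, hh) in enumerate(details, start=1):
        subbands += [lh, hl, hh]
        names += [f"LH{j}", f"HL{j}", f"HH{j}"]
    return DecompositionStack(subbands=subbands, names=names, level=level)


def masked_feature_matrix(
    stack: DecompositionStack, mask: np.ndarray
) -> FeatureMatrix:
    """Gather the subband values of every masked pixel into an (n, d) matrix.

    Rows correspond one-to-one with the True pixels of the mask in raster
    order; columns follow the stack's subband order.
    """
    mask = np.asarray(mask, bool)
    shape = stack.subbands[0].shape
    if mask.shape != shape:
        raise ValueError(f"mask shape {mask.shape} != subband shape {shape}")
    if not mask.any():
        raise ValueError("empty mask: no pixels to extract")
    rows, cols = np.nonzero(mask)  # raster order
    values = np.column_stack([band[rows, cols] for band in stack.subbands])
    return FeatureMatrix(
        values=values,
        pixel_index=np.column_stack([rows, cols]),
        feature_names=list(stack.names),
    )
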