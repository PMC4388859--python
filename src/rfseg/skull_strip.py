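"""Skull stripping by intensity thresholding and mathematical morphology.

The brain mask is produced in eleven steps: median filtering, a global mean
threshold ``T_i``, a skull bounding rectangle, a refined mean ``T_f`` inside
the rectangle, a membrane (meninges) mean ``T`` used to binarize, a 13x13
opening to detach the skull, retention of the largest connected component,
and a 21x21 closing to fill gaps in the intracranial region.  The procedure
rests on the T1 intensity ordering background < membrane < brain < skull.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import disk as _disk
from skimage.morphology import octagon as _octagon

logger = logging.getLogger(__name__)

__all__ = [
    "SkullStripParams",
    "SkullStripTrace",
    "median_filter",
    "initial_threshold",
    "skull_bounding_rect",
    "final_threshold",
    "membrane_threshold",
    "binarize",
    "structuring_element",
    "morph_open",
    "morph_close",
    "largest_component",
    "strip_skull",
]


@dataclass(frozen=True)
class SkullStripParams:
    """Tunables of the skull-stripping procedure.

    Defaults are the published ones: 3x3 median window, 13x13 opening,
    21x21 closing, octagonal structuring element, 8-connectivity.
    """

    median_window: int = 3
    open_size: int = 13
    close_size: int = 21
    structuring_shape: str = "octagon"  # octagon | square | disk
    connectivity: int = 8  # 4 | 8
    membrane_floor: float = 0.0  # exclusive lower bound of the membrane set

    def __post_init__(self) -> None:
        for name in ("median_window", "open_size", "close_size"):
            v = getattr(self, name)
            if v < 1 or v % 2 == 0:
                raise ValueError(f"{name} must be odd and >= 1, got {v}")
        if self.structuring_shape not in ("octagon", "square", "disk"):
            raise ValueError(f"unknown structuring_shape {self.structuring_shape!r}")
        if self.connectivity not in (4, 8):
            raise ValueError(f"connectivity must be 4 or 8, got {self.connectivity}")


@dataclass
class SkullStripTrace:
    """Every intermediate of the stripping procedure, for inspection."""

    T_i: float = float("nan")
    rect: tuple[int, int, int, int] | None = None  # (top, bottom, left, right)
    T_f: float = float("nan")
    T: float = float("nan")
    filtered: np.ndarray | None = None
    binary: np.ndarray | None = None
    opened: np.ndarray | None = None
    largest: np.ndarray | None = None
    closed: np.ndarray | None = None
    notes: list[str] = field(default_factory=list)

    def report(self) -> dict:
        """JSON-serializable summary (thresholds and rectangle)."""
        return {
            "T_i": self.T_i,
            "T_f": self.T_f,
            "T": self.T,
            "rect": None if self.rect is None else list(self.rect),
            "notes": list(self.notes),
        }


def median_filter(image: np.ndarray, window: int = 3) -> np.ndarray:
    """Median filter with edge-replicated borders."""
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 1, got {window}")
    return ndi.median_filter(np.asarray(image, float), size=window, mode="nearest")


def initial_threshold(image: np.ndarray) -> float:
    """Arithmetic mean intensity of the whole image (``T_i``)."""
    image = np.asarray(image, float)
    if image.size == 0:
        raise ValueError("empty image")
    return float(image.mean())


def skull_bounding_rect(image: np.ndarray, T_i: float) -> tuple[int, int, int, int]:
    """Bounding rectangle of all pixels brighter than ``T_i``.

    The skull is the brightest structure, so the first/last row and column
    containing any pixel above the global mean delimit it.  Returns the
    inclusive ``(top, bottom, left, right)`` rectangle.
    """
    bright = np.asarray(image, float) > T_i
    rows = np.flatnonzero(bright.any(axis=1))
    cols = np.flatnonzero(bright.any(axis=0))
    if rows.size == 0:
        raise ValueError("no skull found: no pixel exceeds the initial threshold")
    return int(rows[0]), int(rows[-1]), int(cols[0]), int(cols[-1])


def final_threshold(image: np.ndarray, rect: tuple[int, int, int, int]) -> float:
    """Mean intensity inside the (inclusive) rectangle (``T_f``)."""
    top, bottom, left, right = rect
    image = np.asarray(image, float)
    M, N = image.shape
    if not (0 <= top <= bottom < M and 0 <= left <= right < N):
        raise ValueError(f"rect {rect} outside image bounds {image.shape}")
    return float(image[top : bottom + 1, left : right + 1].mean())


def membrane_threshold(
    image: np.ndarray,
    rect: tuple[int, int, int, int],
    T_f: float,
    floor: float = 0.0,
) -> float:
    """Mean intensity of the membrane pixel set (``T``).

    Membrane (meninges) pixels are darker than the skull-dominated mean
    ``T_f``; operationally the set is every pixel inside the rectangle with
    ``floor < intensity < T_f``.  The exclusive lower bound (default 0) keeps
    pure black background in the rectangle corners from dragging the mean
    down.  If the set is empty, falls back to ``T_f / 2`` with a warning.
    """
    top, bottom, left, right = rect
    patch = np.asarray(image, float)[top : bottom + 1, left : right + 1]
    membrane = patch[(patch > floor) & (patch < T_f)]
    if membrane.size == 0:
        logger.warning(
            "membrane set empty (floor=%g, T_f=%g); falling back to T = T_f/2",
            floor,
            T_f,
        )
        return float(T_f) / 2.0
    return float(membrane.mean())


def binarize(image: np.ndarray, T: float) -> np.ndarray:
    """Strict threshold: ``True`` where intensity > T."""
    return np.asarray(image, float) > T


def structuring_element(size: int, shape: str = "octagon") -> np.ndarray:
    """Boolean structuring element inscribed in a ``size x size`` box.

    The octagon is the standard discrete octagon (as used by morphological
    toolboxes); square and disk are offered because the published method does
    not pin down the octagon's exact vertex offsets.
    """
    if size < 1 or size % 2 == 0:
        raise ValueError(f"size must be odd and >= 1, got {size}")
    if shape == "square":
        return np.ones((size, size), dtype=bool)
    if shape == "disk":
        return _disk(size // 2).astype(bool)
    if shape == "octagon":
        if size < 3:
            return np.ones((1, 1), dtype=bool)
        # octagon(m, n) spans m + 2n; pick the most octagon-like split.
        n = max(1, size // 3)
        m = size - 2 * n
        if m < 1:
            n, m = (size - 1) // 2, 1
        return _octagon(m, n).astype(bool)
    raise ValueError(f"unknown structuring shape {shape!r}")


def morph_open(mask: np.ndarray, size: int, shape: str = "octagon") -> np.ndarray:
    """Binary opening (erosion then dilation)."""
    selem = structuring_element(size, shape)
    return ndi.binary_opening(np.asarray(mask, bool), structure=selem)


def morph_close(mask: np.ndarray, size: int, shape: str = "octagon") -> np.ndarray:
    """Binary closing (dilation then erosion)."""
    selem = structuring_element(size, shape)
    return ndi.binary_closing(np.asarray(mask, bool), structure=selem)


def largest_component(mask: np.ndarray, connectivity: int = 8) -> np.ndarray:
    """Keep only the largest connected component.

    Ties are broken toward the component whose first pixel in raster order
    comes first (``ndi.label`` numbers components in raster order and
    ``argmax`` returns the lowest tied label).
    """
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("empty mask: no connected component to keep")
    structure = np.ones((3, 3), bool) if connectivity == 8 else None
    labeled, n = ndi.label(mask, structure=structure)
    areas = np.bincount(labeled.ravel())
    areas[0] = 0
    return labeled == int(areas.argmax())


def strip_skull(
    image: np.ndarray, params: SkullStripParams | None = None
) -> tuple[np.ndarray, SkullStripTrace]:
    """Run the full eleven-step skull-stripping procedure.

    Returns the boolean brain mask and a trace of every intermediate.
    Fails with ``ValueError`` on images where no skull can be located
    (e.g. constant images).
    """
    if params is None:
        params = SkullStripParams()
    image = np.asarray(image, float)
    trace = SkullStripTrace()

    trace.filtered = median_filter(image, params.median_window)
    trace.T_i = initial_threshold(trace.filtered)
    trace.rect = skull_bounding_rect(trace.filtered, trace.T_i)
    trace.T_f = final_threshold(trace.filtered, trace.rect)
    trace.T = membrane_threshold(
        trace.filtered, trace.rect, trace.T_f, floor=params.membrane_floor
    )
    if trace.T >= trace.T_f:
        trace.notes.append("membrane mean T >= T_f")
    trace.binary = binarize(trace.filtered, trace.T)
    trace.opened = morph_open(trace.binary, params.open_size, params.structuring_shape)
    if not trace.opened.any():
        raise ValueError("opening removed every foreground pixel; no brain found")
    trace.largest = largest_component(trace.opened, params.connectivity)
    trace.closed = morph_close(
        trace.largest, params.close_size, params.structuring_shape
    )
    mask = trace.closed
    if not mask.any():
        raise ValueError("empty brain mask after closing")
    return mask, trace
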