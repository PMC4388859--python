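"""Grayscale image and label-map I/O.

Images are plain 2-D ``float`` NumPy arrays of non-negative intensities on
their native scale (no rescaling to [0, 1] or [0, 255]); the skull-strip
thresholds are means of raw intensities, so any fixed rescaling would not
change behaviour and is avoided for transparency.  Coordinates are row-major,
0-based ``(row, col)`` everywhere in this package.
"""

from __future__ import annotations

import os

import imageio.v3 as iio
import numpy as np

__all__ = ["read_gray", "write_gray", "write_label_image", "middle_slice"]

_NIFTI_SUFFIXES = (".nii", ".nii.gz")


class FormatError(ValueError):
    """Raised for images whose layout the pipeline cannot use."""


def middle_slice(volume: np.ndarray, slice_axis: int = -1) -> np.ndarray:
    """Extract the middle slice ``index = depth // 2`` of a 3-D volume.

    The slice axis defaults to the last array axis; volumes with a different
    layout can override it.
    """
    volume = np.asarray(volume)
    if volume.ndim != 3:
        raise FormatError(f"expected a 3-D volume, got shape {volume.shape}")
    volume = np.moveaxis(volume, slice_axis, -1)
    return np.ascontiguousarray(volume[..., volume.shape[-1] // 2])


def read_gray(path: str | os.PathLike, slice_axis: int = -1) -> np.ndarray:
    """Read a single-channel image (PGM/PNG) or NIfTI volume as float.

    Intensities are cast to float without rescaling, so a 16-bit PNG keeps
    its native values.  For a 3-D volume the middle slice along
    ``slice_axis`` is returned.

    Raises
    ------
    FormatError
        If the image has colour channels or the volume is not 3-D.
    """
    spath = str(path)
    if spath.endswith(_NIFTI_SUFFIXES):
        import nibabel as nib

        data = np.asanyarray(nib.load(spath).dataobj)
        img = middle_slice(data, slice_axis=slice_axis)
    else:
        img = iio.imread(spath)
        if img.ndim == 3:
            raise FormatError(
                f"{spath!r} is multi-channel (shape {img.shape}); "
                "a single-channel grayscale image is required"
            )
        if img.ndim != 2:
            raise FormatError(f"{spath!r} has unsupported shape {img.shape}")
    out = np.ascontiguousarray(img, dtype=float)
    if not np.isfinite(out).all():
        raise FormatError(f"{spath!r} contains non-finite intensities")
    return out


def write_gray(image: np.ndarray, path: str | os.PathLike) -> None:
    """Write a 2-D integer-valued image as 8- or 16-bit PNG/PGM."""
    image = np.asarray(image)
    if image.ndim != 2:
        raise FormatError(f"expected a 2-D image, got shape {image.shape}")
    hi = image.max(initial=0)
    dtype = np.uint8 if hi <= 255 else np.uint16
    iio.imwrite(str(path), image.astype(dtype))


def write_label_image(labels: np.ndarray, path: str | os.PathLike) -> None:
    """Write a label map (small non-negative ints, 0 = background) to PNG/PGM.

    At most 255 distinct labels are supported so the file stays 8-bit and
    each label keeps a distinct gray level.
    """
    labels = np.asarray(labels)
    if labels.ndim != 2:
        raise FormatError(f"expected a 2-D label map, got shape {labels.shape}")
    distinct = np.unique(labels)
    if distinct.size > 255:
        raise ValueError(f"{distinct.size} distinct labels exceed the 255 limit")
    if labels.min(initial=0) < 0 or labels.max(initial=0) > 255:
        raise ValueError("labels must lie in [0, 255]")
    iio.imwrite(str(path), labels.astype(np.uint8))
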