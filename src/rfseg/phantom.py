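"""Ground-truthed synthetic head phantoms for end-to-end testing.

The phantom emulates the structure the segmentation method assumes: a dark
background, a bright skull ring, a darker membrane (meninges) band between
skull and brain, and three tissue wedges inside the brain disk that differ
in base intensity (T1-like CSF < GM < WM contrast) *and* in texture —
smooth, a low-frequency grating, and a high-frequency grating (or filtered
noise) — so that each class carries a distinct subband energy signature.
The intensity ordering background < membrane < tissues < skull is enforced,
which is the precondition of the mean-threshold skull stripper.

Textures are zero-mean additive, so they change a class's subband energies
without moving its mean.  MR magnitude noise is Rician; Gaussian is the
default for test simplicity and a Rician option is provided.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TissueSpec", "PhantomSpec", "make_phantom", "make_cloud_fixture"]


@dataclass(frozen=True)
class TissueSpec:
    """Appearance of one tissue class.

    ``texture`` is one of ``smooth`` (base level only), ``grating``
    (additive sinusoid of the given period, in pixels, and orientation, in
    radians), or ``noise`` (Gaussian-filtered white noise of the given
    correlation length).
    """

    level: float
    texture: str = "smooth"  # smooth | grating | noise
    amplitude: float = 0.0
    period: float = 16.0
    orientation: float = 0.0
    correlation_length: float = 2.0

    def __post_init__(self) -> None:
        if self.texture not in ("smooth", "grating", "noise"):
            raise ValueError(f"unknown texture kind {self.texture!r}")


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and appearance of the synthetic head.

    Radii are in pixels from the image centre.  The membrane band spans
    ``(brain_radius, brain_radius + membrane_width]`` and the skull annulus
    ``(skull_inner, skull_outer]``; the two must not overlap.
    """

    size: int = 256
    seed: int = 0
    background_level: float = 0.0
    membrane_level: float = 50.0
    skull_level: float = 250.0
    brain_radius: float = 90.0
    membrane_width: float = 8.0
    skull_inner: float = 98.0
    skull_outer: float = 110.0
    tissues: tuple[TissueSpec, ...] = (
        TissueSpec(level=100.0, texture="smooth"),
        TissueSpec(level=145.0, texture="grating", amplitude=8.0, period=16.0),
        TissueSpec(
            level=190.0, texture="grating", amplitude=8.0, period=4.0, orientation=0.9
        ),
    )
    noise_sigma: float = 3.0
    noise_kind: str = "gaussian"  # gaussian | rician

    def __post_init__(self) -> None:
        if self.size < 16:
            raise ValueError("size must be >= 16")
        if self.skull_inner < self.brain_radius + self.membrane_width:
            raise ValueError("skull annulus overlaps the membrane band")
        if not self.skull_inner < self.skull_outer <= self.size / 2:
            raise ValueError("skull annulus must fit inside the image")
        levels = [t.level for t in self.tissues]
        if not (
            self.background_level < self.membrane_level < min(levels)
            and max(levels) < self.skull_level
        ):
            raise ValueError(
                "intensity ordering background < membrane < tissues < skull required"
            )
        if self.noise_kind not in ("gaussian", "rician"):
            raise ValueError(f"unknown noise kind {self.noise_kind!r}")


def _texture_field(
    tissue: TissueSpec, shape: tuple[int, int], rng: np.random.Generator
) -> np.ndarray:
    if tissue.texture == "smooth" or tissue.amplitude == 0.0:
        return np.zeros(shape)
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    if tissue.texture == "grating":
        theta = tissue.orientation
        phase = 2.0 * np.pi * (np.cos(theta) * xx + np.sin(theta) * yy) / tissue.period
        return tissue.amplitude * np.sin(phase)
    # filtered white noise with the requested correlation length
    from scipy.ndimage import gaussian_filter

    white = rng.standard_normal(shape)
    smooth = gaussian_filter(white, sigma=tissue.correlation_length, mode="wrap")
    smooth /= smooth.std()
    return tissue.amplitude * smooth


def make_phantom(
    spec: PhantomSpec | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Generate a phantom image with its ground truth.

    Returns ``(image, truth_labels, truth_brain)`` where truth labels are 0
    for everything outside the brain and 1..K for the tissue wedges, and
    ``truth_brain`` is the boolean union of the tissue wedges (the membrane
    is not part of the brain).  Deterministic for a fixed spec/seed.
    """
    if spec is None:
        spec = PhantomSpec()
    rng = np.random.default_rng(spec.seed)
    n = spec.size
    centre = (n - 1) / 2.0
    yy, xx = np.mgrid[0:n, 0:n]
    r = np.hypot(yy - centre, xx - centre)
    theta = np.arctan2(yy - centre, xx - centre)  # [-pi, pi)

    image = np.full((n, n), spec.background_level, dtype=float)
    labels = np.zeros((n, n), dtype=np.int64)

    membrane = (r > spec.brain_radius) & (
        r <= spec.brain_radius + spec.membrane_width
    )
    skull = (r > spec.skull_inner) & (r <= spec.skull_outer)
    image[membrane] = spec.membrane_level
    image[skull] = spec.skull_level

    brain = r <= spec.brain_radius
    k = len(spec.tissues)
    wedge_idx = np.floor((theta + np.pi) / (2.0 * np.pi / k)).astype(int)
    wedge_idx = np.clip(wedge_idx, 0, k - 1)
    for i, tissue in enumerate(spec.tissues):
        region = brain & (wedge_idx == i)
        field = _texture_field(tissue, (n, n), rng)
        image[region] = tissue.level + field[region]
        labels[region] = i + 1

    if spec.noise_sigma > 0:
        if spec.noise_kind == "gaussian":
            image = image + rng.normal(0.0, spec.noise_sigma, size=(n, n))
        else:  # Rician: magnitude of a complex Gaussian around the signal
            re = image + rng.normal(0.0, spec.noise_sigma, size=(n, n))
            im = rng.normal(0.0, spec.noise_sigma, size=(n, n))
            image = np.hypot(re, im)
    image = np.clip(image, 0.0, None)  # intensities stay non-negative
    return image, labels, brain


def make_cloud_fixture(
    c: int,
    n_per: int,
    separation: float,
    sigma: float,
    seed: int | None = None,
    dim: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Isotropic Gaussian clouds at equal pairwise centre distance.

    Centres sit on scaled standard-basis vectors (a regular simplex), so
    every pair of centres is exactly ``separation`` apart.  Returns the
    (c * n_per, dim) sample matrix and its integer labels.
    """
    if c < 1 or n_per < 1:
        raise ValueError("c and n_per must be >= 1")
    rng = np.random.default_rng(seed)
    dim = c if dim is None else dim
    if dim < c:
        raise ValueError("dim must be >= c for an equidistant simplex")
    centres = np.zeros((c, dim))
    for i in range(c):
        centres[i, i] = separation / np.sqrt(2.0)
    X = np.concatenate(
        [centres[i] + sigma * rng.standard_normal((n_per, dim)) for i in range(c)]
    )
    labels = np.repeat(np.arange(c), n_per)
    return X, labels
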