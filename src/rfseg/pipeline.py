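"""End-to-end segmentation pipeline.

Five stages: (1) skull stripping to a brain mask, (2) undecimated wavelet
decomposition of the input image, (3) masked per-pixel feature vectors,
(4) unsupervised MRMS feature selection, (5) robust rough-fuzzy c-means on
the selected features.  The result is a label image with 0 outside the mask
and cluster ids 1..c inside, plus a bundle of reports (skull-strip trace,
selection trace, cluster report).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cluster import rrfcm
from .mrms import default_m, select
from .skull_strip import SkullStripParams, strip_skull
from .wavelet import masked_feature_matrix, undecimated_decompose

__all__ = ["PipelineConfig", "segment", "labels_from_clusters"]


@dataclass(frozen=True)
class PipelineConfig:
    """Settings of the full pipeline.

    ``n_features=None`` applies the default rule ``m = ceil(sqrt(d))``
    (3 of the 7 level-2 subbands).  ``scale_features`` optionally z-scores
    the selected features before clustering; off by default because the
    approximation subband's dominant magnitude is part of the signal.
    """

    level: int = 2
    n_features: int | None = None
    n_clusters: int = 3
    strip: SkullStripParams = field(default_factory=SkullStripParams)
    boundary_mode: str = "symmetric"
    m1: float = 2.0
    m2: float = 2.0
    omega: float = 0.99
    K: float = 1.0
    max_iter: int = 100
    tol: float = 1e-5
    seed: int = 0
    scale_features: bool = False


def labels_from_clusters(
    hard_labels: np.ndarray, mask: np.ndarray, shape: tuple[int, int]
) -> np.ndarray:
    """Scatter per-object cluster ids (+1) back into the mask positions.

    Objects are in raster order over the mask's True pixels; label 0 marks
    everything outside the mask.
    """
    mask = np.asarray(mask, bool)
    if mask.shape != tuple(shape):
        raise ValueError(f"mask shape {mask.shape} != {tuple(shape)}")
    hard_labels = np.asarray(hard_labels)
    n = int(mask.sum())
    if hard_labels.shape != (n,):
        raise ValueError(f"{hard_labels.shape[0]} labels for {n} mask pixels")
    out = np.zeros(shape, dtype=np.int64)
    out[mask] = hard_labels + 1
    return out


def segment(
    image: np.ndarray, config: PipelineConfig | None = None
) -> tuple[np.ndarray, dict]:
    """Segment a grayscale head image into ``n_clusters`` tissue classes.

    Returns ``(label_image, reports)``.  The reports dict carries the
    skull-strip thresholds, the feature dimensions d and m, the selected
    subband names and selection trace, and the cluster report.
    """
    if config is None:
        config = PipelineConfig()
    image = np.asarray(image, float)

    mask, trace = strip_skull(image, config.strip)
    stack = undecimated_decompose(image, config.level, mode=config.boundary_mode)
    features = masked_feature_matrix(stack, mask)

    d = features.d
    m = default_m(d) if config.n_features is None else int(config.n_features)
    selection = select(features.values, m)
    X = features.values[:, selection.selected]
    if config.scale_features:
        std = X.std(axis=0)
        std[std == 0] = 1.0
        X = (X - X.mean(axis=0)) / std

    result = rrfcm(
        X,
        c=config.n_clusters,
        m1=config.m1,
        m2=config.m2,
        omega=config.omega,
        K=config.K,
        max_iter=config.max_iter,
        tol=config.tol,
        seed=config.seed,
    )
    label_image = labels_from_clusters(result.labels, mask, image.shape)

    reports = {
        "skull_strip": trace.report(),
        "n_pixels": features.n,
        "d": d,
        "m": len(selection.selected),
        "selected_features": [features.feature_names[i] for i in selection.selected],
        "selection_trace": selection.trace,
        "relevance": {
            name: float(g)
            for name, g in zip(features.feature_names, selection.relevance)
        },
        "cluster": result.report(),
    }
    return label_image, reports
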