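"""Polarization super-pixels: feature-space compression of ROI pixels.

Pixels are grouped by minibatch k-means in standardized normalized-element
space — no spatial contiguity constraint — so each super-pixel is a
feature-space Voronoi cell represented by its centroid, its member-pixel
back-map, and the mean of its members' polarization basis parameters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from sklearn.cluster import MiniBatchKMeans

from .mueller import FeatureImage
from .pbp import PBPImage

logger = logging.getLogger(__name__)

__all__ = [
    "SuperPixelSet",
    "standardize",
    "build_superpixels",
    "superpixel_pbp_means",
    "compression_orders_of_magnitude",
]


def compression_orders_of_magnitude(n_pixels: int, k: int) -> float:
    """Base-10 log of the pixel-to-super-pixel compression ratio."""
    if n_pixels <= 0 or k <= 0:
        raise ValueError("n_pixels and k must be positive")
    return float(np.log10(n_pixels / k))


@dataclass
class SuperPixelSet:
    """k feature-space centroids with member back-maps for one ROI."""

    roi_id: str
    k: int
    centroids: np.ndarray           # (k, n_features) in standardized space
    member_index: list[np.ndarray]  # per super-pixel, (n_i, 2) of (row, col)
    counts: np.ndarray              # (k,)
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    seed: int
    image_shape: tuple[int, int] = (0, 0)
    mean_pbp: Optional[np.ndarray] = None  # (k, P)
    pbp_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.k != len(self.member_index) or self.k != len(self.counts):
            raise ValueError("k, member_index and counts are inconsistent")
        for i, (n, members) in enumerate(zip(self.counts, self.member_index)):
            if n != len(members):
                raise ValueError(f"super-pixel {i}: counts[i] != len(member_index[i])")

    @property
    def n_pixels(self) -> int:
        return int(self.counts.sum())

    def label_image(self, shape: tuple[int, int]) -> np.ndarray:
        """(H, W) array of super-pixel indices; -1 outside all members."""
        lab = np.full(shape, -1, dtype=np.int32)
        for i, members in enumerate(self.member_index):
            lab[members[:, 0], members[:, 1]] = i
        return lab


def standardize(features: FeatureImage) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-feature zero-mean unit-variance scaling over valid pixels.

    Uses the population standard deviation.  Zero-variance features are
    centered only (scale 1, logged).  Returns the standardized (H, W, C)
    stack (NaN at masked pixels) plus the (mean, scale) stats.
    """
    mask = features.mask
    n_valid = int(mask.sum())
    if n_valid == 0:
        raise ValueError("all pixels are masked; nothing to standardize")
    if n_valid < 2:
        raise ValueError("need at least 2 valid pixels to standardize")
    X = features.features[mask]
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    degenerate = scale == 0
    if degenerate.any():
        logger.warning(
            "%s: %d constant feature(s); centering only",
            features.roi_id or "<roi>",
            int(degenerate.sum()),
        )
        scale = np.where(degenerate, 1.0, scale)
    out = np.full_like(features.features, np.nan)
    out[mask] = (X - mean) / scale
    return out, mean, scale


def build_superpixels(
    features: FeatureImage,
    k: int = 1024,
    seed: int = 0,
    batch_size: int = 4096,
    n_init: int = 10,
    max_iter: int = 300,
) -> SuperPixelSet:
    """Compress an ROI's valid pixels into k feature-space super-pixels.

    Minibatch k-means fits the centroids on standardized features; the
    final assignment is the exact nearest centroid (Euclidean, ties to
    the lowest index).  Empty clusters are dropped and k reported as the
    realized count.  Deterministic given ``seed``.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    std, mean, scale = standardize(features)
    mask = features.mask
    rows, cols = np.nonzero(mask)
    X = std[mask]
    n_valid = X.shape[0]
    if n_valid < k:
        logger.info(
            "%s: only %d valid pixels; lowering k from %d",
            features.roi_id or "<roi>", n_valid, k,
        )
        k = n_valid
    if k == n_valid:
        # Identity compression: every pixel is its own super-pixel.
        centroids = X.copy()
    else:
        km = MiniBatchKMeans(
            n_clusters=k,
            random_state=seed,
            batch_size=batch_size,
            n_init=n_init,
            max_iter=max_iter,
        )
        km.fit(X)
        centroids = km.cluster_centers_

    # Exact nearest-centroid assignment (chunked to bound memory).
    labels = np.empty(n_valid, dtype=np.int64)
    chunk = max(1, 2**22 // max(1, k))
    for s in range(0, n_valid, chunk):
        d2 = (
            np.einsum("ij,ij->i", X[s : s + chunk], X[s : s + chunk])[:, None]
            - 2.0 * X[s : s + chunk] @ centroids.T
            + np.einsum("ij,ij->i", centroids, centroids)[None, :]
        )
        labels[s : s + chunk] = np.argmin(d2, axis=1)

    counts_all = np.bincount(labels, minlength=k)
    keep = np.flatnonzero(counts_all > 0)
    if len(keep) < k:
        logger.info(
            "%s: dropping %d empty super-pixel(s)",
            features.roi_id or "<roi>", k - len(keep),
        )
    remap = np.full(k, -1, dtype=np.int64)
    remap[keep] = np.arange(len(keep))
    labels = remap[labels]
    centroids = centroids[keep]
    k_real = len(keep)

    order = np.argsort(labels, kind="stable")
    coords = np.column_stack([rows, cols])[order]
    counts = np.bincount(labels, minlength=k_real)
    offsets = np.concatenate([[0], np.cumsum(counts)])
    member_index = [coords[offsets[i] : offsets[i + 1]] for i in range(k_real)]

    return SuperPixelSet(
        roi_id=features.roi_id,
        k=k_real,
        centroids=centroids,
        member_index=member_index,
        counts=counts,
        scaler_mean=mean,
        scaler_scale=scale,
        seed=seed,
        image_shape=features.shape,
    )


def superpixel_pbp_means(sp: SuperPixelSet, pbp: PBPImage) -> SuperPixelSet:
    """Fill ``mean_pbp`` with the arithmetic mean PBP vector per super-pixel.

    The count-weighted overall mean equals the whole-ROI pixel mean.
    Pixels masked in the PBP image (undefined parameters) are excluded
    from their super-pixel's average.
    """
    if sp.roi_id and pbp.roi_id and sp.roi_id != pbp.roi_id:
        raise ValueError(f"ROI mismatch: {sp.roi_id!r} vs {pbp.roi_id!r}")
    if sp.image_shape != (0, 0) and tuple(sp.image_shape) != pbp.shape:
        raise ValueError(f"shape mismatch: {sp.image_shape} vs {pbp.shape}")
    P = len(pbp.names)
    mean_pbp = np.full((sp.k, P), np.nan)
    for i, members in enumerate(sp.member_index):
        vals = pbp.values[members[:, 0], members[:, 1]]
        ok = pbp.mask[members[:, 0], members[:, 1]]
        if ok.any():
            mean_pbp[i] = vals[ok].mean(axis=0)
    sp.mean_pbp = mean_pbp
    sp.pbp_names = tuple(pbp.names)
    return sp
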