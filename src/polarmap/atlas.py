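"""Pooled super-pixel atlas: 2D embedding, trimming, clustering, spreading.

Super-pixels pooled across ROIs are standardized globally, embedded to 2D
with UMAP (Canberra metric, 30 neighbors by default), low-density regions
on a regular grid are trimmed before single-linkage clustering, and the
trimmed points recover their labels by semi-supervised label spreading.
Stability diagnostics (convergence with data volume, leave-one-patient-out
projection distance) operate on patient-grouped feature rows.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.linalg import orthogonal_procrustes
from scipy.stats import spearmanr
from sklearn.neighbors import NearestNeighbors
from sklearn.semi_supervised import LabelSpreading

logger = logging.getLogger(__name__)

__all__ = [
    "AtlasModel",
    "DensityGrid",
    "canberra",
    "fit_atlas",
    "project",
    "grid_trim",
    "cluster_single_linkage",
    "cut_largest_gap",
    "spread_labels",
    "convergence_curve",
    "holdout_distance",
    "rigid_align",
]


def canberra(x: np.ndarray, y: np.ndarray) -> float:
    """Canberra distance: sum |x_i - y_i| / (|x_i| + |y_i|), 0/0 terms -> 0."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    num = np.abs(x - y)
    den = np.abs(x) + np.abs(y)
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return float(terms.sum())


@dataclass
class DensityGrid:
    """Point counts on a regular 2D grid with half-open bins (last closed)."""

    extent: tuple[float, float, float, float]  # xmin, xmax, ymin, ymax
    nx: int
    ny: int
    counts: np.ndarray  # (nx, ny)

    def bin_of(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        xmin, xmax, ymin, ymax = self.extent
        ix = np.floor((points[:, 0] - xmin) / (xmax - xmin) * self.nx).astype(int)
        iy = np.floor((points[:, 1] - ymin) / (ymax - ymin) * self.ny).astype(int)
        return np.clip(ix, 0, self.nx - 1), np.clip(iy, 0, self.ny - 1)


@dataclass
class AtlasModel:
    """Fitted embedding, trimming mask, linkage tree and cluster labels."""

    embedding: np.ndarray                      # (n, 2)
    source_keys: list[tuple[str, int]]         # (roi_id, superpixel index) per row
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    fitted_projector: object                   # opaque; exposes .transform
    params: dict = field(default_factory=dict)
    retained_mask: Optional[np.ndarray] = None
    density_grid: Optional[DensityGrid] = None
    linkage_tree: Optional[np.ndarray] = None  # scipy (m, 4) linkage of retained pts
    labels: Optional[np.ndarray] = None        # (n,), -1 = unassigned

    @property
    def n_points(self) -> int:
        return self.embedding.shape[0]

    def n_clusters(self) -> int:
        if self.labels is None:
            return 0
        return int((np.unique(self.labels[self.labels >= 0])).size)

    def principal_clusters(self, min_frac: float = 0.01) -> np.ndarray:
        """Cluster ids holding at least ``min_frac`` of labeled points."""
        if self.labels is None:
            return np.array([], dtype=int)
        lab = self.labels[self.labels >= 0]
        ids, counts = np.unique(lab, return_counts=True)
        return ids[counts >= min_frac * lab.size]


def _global_standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale = np.where(scale == 0, 1.0, scale)
    return (X - mean) / scale, mean, scale


def fit_atlas(
    rows: np.ndarray,
    source_keys: Optional[Sequence[tuple[str, int]]] = None,
    n_neighbors: int = 30,
    metric: str = "canberra",
    seed: int = 0,
    min_dist: float = 0.1,
) -> AtlasModel:
    """Standardize pooled feature rows globally and embed them to 2D.

    The fitted projector is retained so unseen rows can be transformed
    into the same axes.  Deterministic given ``seed``.
    """
    import umap  # deferred: numba jit import is slow

    rows = np.asarray(rows, dtype=float)
    if rows.ndim != 2:
        raise ValueError("rows must be a 2D array")
    if not np.isfinite(rows).all():
        raise ValueError("feature rows must be finite (drop NaN rows first)")
    if rows.shape[0] < n_neighbors + 1:
        raise ValueError(
            f"need at least n_neighbors + 1 = {n_neighbors + 1} rows, got {rows.shape[0]}"
        )
    X, mean, scale = _global_standardize(rows)
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", module="umap")
        warnings.filterwarnings("ignore", category=UserWarning)
        reducer = umap.UMAP(
            n_components=2,
            n_neighbors=n_neighbors,
            metric=metric,
            min_dist=min_dist,
            random_state=seed,
        )
        emb = reducer.fit_transform(X)
    if source_keys is None:
        source_keys = [("", i) for i in range(rows.shape[0])]
    return AtlasModel(
        embedding=np.asarray(emb, dtype=float),
        source_keys=list(source_keys),
        scaler_mean=mean,
        scaler_scale=scale,
        fitted_projector=reducer,
        params={
            "metric": metric,
            "n_neighbors": n_neighbors,
            "min_dist": min_dist,
            "seed": seed,
        },
    )


def project(model: AtlasModel, rows: np.ndarray) -> np.ndarray:
    """Project unseen feature rows into the fitted atlas axes."""
    rows = np.asarray(rows, dtype=float)
    if rows.ndim != 2 or rows.shape[1] != model.scaler_mean.shape[0]:
        raise ValueError(
            f"expected (m, {model.scaler_mean.shape[0]}) rows, got {rows.shape}"
        )
    X = (rows - model.scaler_mean) / model.scaler_scale
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", module="umap")
        warnings.filterwarnings("ignore", category=UserWarning)
        return np.asarray(model.fitted_projector.transform(X), dtype=float)


def grid_trim(
    points: np.ndarray,
    nx: int = 200,
    ny: int = 200,
    cutoff: int = 11,
) -> tuple[np.ndarray, DensityGrid]:
    """Retain points whose grid bin holds at least ``cutoff`` points.

    The grid extent is the bounding box padded by 1e-9 of the range so
    every point falls in a bin.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 2 or points.shape[0] < 1:
        raise ValueError("points must be a non-empty (n, 2) array")
    xmin, ymin = points.min(axis=0)
    xmax, ymax = points.max(axis=0)
    pad_x = 1e-9 * max(xmax - xmin, 1.0)
    pad_y = 1e-9 * max(ymax - ymin, 1.0)
    grid = DensityGrid(
        extent=(xmin - pad_x, xmax + pad_x, ymin - pad_y, ymax + pad_y),
        nx=nx,
        ny=ny,
        counts=np.zeros((nx, ny), dtype=np.int64),
    )
    ix, iy = grid.bin_of(points)
    np.add.at(grid.counts, (ix, iy), 1)
    retained = grid.counts[ix, iy] >= cutoff
    return retained, grid


def cluster_single_linkage(
    points: np.ndarray, n_clusters: int
) -> tuple[np.ndarray, np.ndarray]:
    """Agglomerate 2D points by minimum inter-cluster pair distance.

    Returns 0-based labels (exactly ``n_clusters`` groups) and the scipy
    linkage tree (merge pairs + distances), serializable as a dendrogram.
    """
    points = np.asarray(points, dtype=float)
    n = points.shape[0]
    if not 1 <= n_clusters <= n:
        raise ValueError(f"n_clusters must be in [1, {n}], got {n_clusters}")
    if n == 1:
        return np.zeros(1, dtype=int), np.empty((0, 4))
    Z = linkage(points, method="single")
    raw = fcluster(Z, t=n_clusters, criterion="maxclust")
    # Relabel to 0..C-1 in order of first appearance for determinism.
    _, labels = np.unique(raw, return_inverse=True)
    return labels.astype(int), Z


def cut_largest_gap(Z: np.ndarray, max_clusters: int = 15) -> int:
    """Pick a cluster count by the largest absolute gap in merge heights.

    For candidate counts c in [2, max_clusters], the gap is the height
    difference between the first merge removed by the cut and the last
    one kept; single-linkage trees of well-separated groups show the
    dominant gap at the true count.  (The absolute gap is used rather
    than the ratio: low-height splinter merges have tiny denominators
    and would dominate a ratio criterion.)
    """
    n = Z.shape[0] + 1
    heights = Z[:, 2]
    best_c, best_gap = 2, -np.inf
    for c in range(2, min(max_clusters, n - 1) + 1):
        kept = heights[n - 1 - c]
        removed = heights[n - c]
        gap = removed - kept
        if gap > best_gap:
            best_gap = gap
            best_c = c
    return best_c


def spread_labels(
    points: np.ndarray,
    labels: np.ndarray,
    n_neighbors: int = 7,
) -> np.ndarray:
    """Propagate labels from labeled to unlabeled (-1) points.

    Graph-based label spreading on a k-NN graph in the 2D embedding with
    hard clamping: labeled points keep their labels exactly.  Any point
    the graph fails to reach falls back to its nearest labeled neighbor.
    """
    points = np.asarray(points, dtype=float)
    labels = np.asarray(labels)
    if points.shape[0] != labels.shape[0]:
        raise ValueError("points and labels must align")
    labeled = labels >= 0
    if not labeled.any():
        raise ValueError("at least one labeled point is required")
    out = labels.astype(int).copy()
    if labeled.all():
        return out

    unique = np.unique(labels[labeled])
    if unique.size == 1:
        out[~labeled] = unique[0]
        return out

    k = min(n_neighbors, points.shape[0] - 1)
    model = LabelSpreading(kernel="knn", n_neighbors=k, alpha=0.2, max_iter=100)
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore")
        model.fit(points, labels)
        spread = model.transduction_.astype(int)
    out[~labeled] = spread[~labeled]

    unreached = out < 0
    if unreached.any():
        nn = NearestNeighbors(n_neighbors=1).fit(points[labeled])
        _, idx = nn.kneighbors(points[unreached])
        out[unreached] = labels[labeled][idx[:, 0]]
    return out


def rigid_align(source: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Orthogonal (rotation/reflection) + translation alignment.

    Returns (R, t) such that ``source @ R + t`` best matches ``target``
    in least squares.  Independently fitted embeddings carry arbitrary
    orientation, so alignment precedes any displacement measurement.
    """
    source = np.asarray(source, dtype=float)
    target = np.asarray(target, dtype=float)
    if source.shape != target.shape:
        raise ValueError("source and target must have matching shapes")
    mu_s = source.mean(axis=0)
    mu_t = target.mean(axis=0)
    R, _ = orthogonal_procrustes(source - mu_s, target - mu_t)
    t = mu_t - mu_s @ R
    return R, t


def _normalized_displacement(
    a: np.ndarray, b: np.ndarray, ranges: np.ndarray
) -> np.ndarray:
    """Per-point Euclidean distance after per-axis range normalization."""
    d = (a - b) / ranges
    return np.linalg.norm(d, axis=1)


def _axis_ranges(emb: np.ndarray) -> np.ndarray:
    r = emb.max(axis=0) - emb.min(axis=0)
    return np.where(r > 0, r, 1.0)


def convergence_curve(
    features_by_patient: Mapping[str, np.ndarray],
    fractions: Sequence[float],
    seed: int = 0,
    align: bool = True,
    **fit_kwargs,
) -> dict[float, float]:
    """Embedding-configuration distance versus training-data fraction.

    For each fraction, the atlas is fitted on that share of patients
    (fixed shuffled order per seed), a common probe set (all rows) is
    projected, rigidly aligned to the full-data fit, and the mean
    per-point displacement normalized by the full fit's axis ranges is
    reported.
    """
    patients = sorted(features_by_patient)
    if len(patients) < 2:
        raise ValueError("need at least two patients")
    for f in fractions:
        if not 0 < f <= 1:
            raise ValueError(f"fraction {f} outside (0, 1]")
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(patients))
    probe = np.vstack([features_by_patient[p] for p in patients])

    full = fit_atlas(probe, seed=seed, **fit_kwargs)
    ref = project(full, probe)
    ranges = _axis_ranges(full.embedding)

    out: dict[float, float] = {}
    for f in sorted(fractions):
        n_pat = max(1, int(np.ceil(f * len(patients))))
        subset = order[:n_pat]
        train = np.vstack([features_by_patient[p] for p in subset])
        nn = min(fit_kwargs.get("n_neighbors", 30), train.shape[0] - 1)
        kw = dict(fit_kwargs)
        kw["n_neighbors"] = nn
        if f >= 1.0:
            sub_proj = ref.copy()
        else:
            sub = fit_atlas(train, seed=seed, **kw)
            sub_proj = project(sub, probe)
        if align:
            R, t = rigid_align(sub_proj, ref)
            sub_proj = sub_proj @ R + t
        out[f] = float(_normalized_displacement(sub_proj, ref, ranges).mean())
    return out


def holdout_distance(
    features_by_patient: Mapping[str, np.ndarray],
    held_out: str,
    seed: int = 0,
    align: bool = True,
    **fit_kwargs,
) -> tuple[float, float]:
    """Leave-one-patient-out projection stability.

    Fits the atlas with and without the held-out patient, projects the
    held-out rows onto both, aligns the two fits using the training
    rows, and returns the mean and variance of the per-row displacement
    normalized by the full fit's axis ranges.
    """
    patients = sorted(features_by_patient)
    if held_out not in features_by_patient:
        raise ValueError(f"unknown patient {held_out!r}")
    if len(patients) < 2:
        raise ValueError("need at least two patients")
    train_pat = [p for p in patients if p != held_out]
    train = np.vstack([features_by_patient[p] for p in train_pat])
    test = np.asarray(features_by_patient[held_out], dtype=float)
    all_rows = np.vstack([train, test])

    full = fit_atlas(all_rows, seed=seed, **fit_kwargs)
    nn = min(fit_kwargs.get("n_neighbors", 30), train.shape[0] - 1)
    kw = dict(fit_kwargs)
    kw["n_neighbors"] = nn
    loo = fit_atlas(train, seed=seed, **kw)

    test_full = project(full, test)
    test_loo = project(loo, test)
    if align:
        anchor_full = project(full, train)
        anchor_loo = project(loo, train)
        R, t = rigid_align(anchor_loo, anchor_full)
        test_loo = test_loo @ R + t
    ranges = _axis_ranges(full.embedding)
    d = _normalized_displacement(test_loo, test_full, ranges)
    return float(d.mean()), float(d.var())
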