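"""Cluster-area-proportion markers: masks, statistics and density maps.

Atlas cluster labels are projected back to the image plane through the
super-pixel back-maps; per-ROI area proportions of each cluster are the
marker statistics, compared across pathology groups by Welch t-tests and
rank-based AUC, and visualized as log-scale density heatmaps on shared
atlas axes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .atlas import DensityGrid
from .superpixel import SuperPixelSet

__all__ = [
    "LabelMask",
    "project_labels_to_mask",
    "area_proportion",
    "marker_table",
    "marker_auc",
    "group_t_test",
    "density_heatmap",
    "marker_report",
    "PERCENTILES",
]

#: Box-whisker percentiles reported per group (whisker/box/median levels).
PERCENTILES = (10, 25, 50, 75, 90)


@dataclass
class LabelMask:
    """Integer label grid: 0 = unassigned/invalid, 1..C = cluster ids."""

    labels: np.ndarray
    roi_id: str = ""

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim != 2 or not np.issubdtype(lab.dtype, np.integer):
            raise ValueError("labels must be a 2D integer grid")
        if (lab < 0).any():
            raise ValueError("mask labels must be non-negative")
        self.labels = lab


def project_labels_to_mask(
    sp: SuperPixelSet,
    atlas_labels: np.ndarray,
    allow_unassigned: bool = False,
) -> LabelMask:
    """Give each member pixel its super-pixel's atlas cluster label (+1).

    ``atlas_labels`` holds one 0-based cluster id per super-pixel of this
    ROI; in the mask they become 1-based with 0 reserved for
    unassigned/invalid pixels.  A negative label is an error unless
    ``allow_unassigned``, in which case those pixels stay 0.
    """
    atlas_labels = np.asarray(atlas_labels)
    if atlas_labels.shape[0] != sp.k:
        raise ValueError(f"expected {sp.k} labels, got {atlas_labels.shape[0]}")
    if (atlas_labels < 0).any() and not allow_unassigned:
        raise ValueError("every super-pixel must carry a cluster label")
    shape = sp.image_shape
    if shape == (0, 0):
        raise ValueError("super-pixel set has no recorded image shape")
    mask = np.zeros(shape, dtype=np.int32)
    for i, members in enumerate(sp.member_index):
        if atlas_labels[i] >= 0:
            mask[members[:, 0], members[:, 1]] = atlas_labels[i] + 1
    return LabelMask(labels=mask, roi_id=sp.roi_id)


def area_proportion(mask: LabelMask, cluster_id: int) -> float:
    """Pixels of ``cluster_id`` divided by the total ROI pixel count.

    The denominator is the full ROI area — unassigned pixels included —
    so per-ROI proportions over all clusters sum to at most 1.
    """
    if cluster_id < 1:
        raise ValueError("cluster_id must be >= 1 (0 is unassigned)")
    lab = mask.labels
    return float((lab == cluster_id).sum() / lab.size)


def marker_table(
    masks: Sequence[LabelMask],
    metadata: Sequence[tuple[str, str, str]],
    cluster_ids: Sequence[int],
) -> pd.DataFrame:
    """Long-format table of (roi_id, patient_id, group, cluster_id, area_proportion)."""
    if len(masks) != len(metadata):
        raise ValueError("masks and metadata must align")
    rows = []
    for mask, (roi_id, patient_id, group) in zip(masks, metadata):
        for cid in cluster_ids:
            rows.append(
                {
                    "roi_id": roi_id,
                    "patient_id": patient_id,
                    "group": group,
                    "cluster_id": int(cid),
                    "area_proportion": area_proportion(mask, cid),
                }
            )
    return pd.DataFrame(rows)


def marker_auc(values: Sequence[float], is_positive: Sequence[bool]) -> float:
    """Probability a random positive exceeds a random negative (ties 1/2).

    Rank-sum formulation of the ROC AUC.
    """
    values = np.asarray(values, dtype=float)
    is_positive = np.asarray(is_positive, dtype=bool)
    if values.shape != is_positive.shape:
        raise ValueError("values and is_positive must align")
    n_pos = int(is_positive.sum())
    n_neg = int((~is_positive).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need at least one positive and one negative")
    ranks = stats.rankdata(values)
    u = ranks[is_positive].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def group_t_test(
    values_a: Sequence[float],
    values_b: Sequence[float],
    equal_var: bool = False,
) -> tuple[float, float]:
    """Two-sided two-sample t-test (Welch by default)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(res.statistic), float(res.pvalue)


def density_heatmap(
    coords: np.ndarray,
    subset_mask: Optional[np.ndarray],
    grid: DensityGrid,
    log_scale: bool = True,
) -> tuple[DensityGrid, np.ndarray]:
    """Bin a subset of embedding points on shared atlas axes.

    Returns the subset's count grid plus the rendered intensity, which
    uses log10(count + 1) when ``log_scale`` so maps from different
    groups are directly comparable.
    """
    coords = np.asarray(coords, dtype=float)
    if subset_mask is None:
        subset_mask = np.ones(coords.shape[0], dtype=bool)
    pts = coords[np.asarray(subset_mask, dtype=bool)]
    if pts.shape[0] < 1:
        raise ValueError("subset contains no points")
    counts = np.zeros((grid.nx, grid.ny), dtype=np.int64)
    ix, iy = grid.bin_of(pts)
    np.add.at(counts, (ix, iy), 1)
    out = DensityGrid(extent=grid.extent, nx=grid.nx, ny=grid.ny, counts=counts)
    image = np.log10(counts + 1.0) if log_scale else counts.astype(float)
    return out, image


def marker_report(
    table: pd.DataFrame,
    groups: Sequence[str],
    contrasts: Sequence[tuple[str, str]] = (),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Box-whisker statistics per cluster x group plus pairwise tests.

    Returns ``(percentile_rows, contrast_rows)``: the five box-whisker
    percentiles (linear interpolation between order statistics), and per
    requested (negative, positive) contrast the Welch p-value and AUC of
    each cluster's area proportion.
    """
    present = set(table["group"].unique())
    missing = [g for g in groups if g not in present]
    if missing:
        raise ValueError(f"unknown group(s) {missing}; present: {sorted(present)}")
    for a, b in contrasts:
        for g in (a, b):
            if g not in present:
                raise ValueError(f"unknown group {g!r} in contrast ({a!r}, {b!r})")

    pct_rows = []
    for (cid, group), sub in table.groupby(["cluster_id", "group"]):
        if group not in groups:
            continue
        vals = sub["area_proportion"].to_numpy()
        row = {"cluster_id": cid, "group": group, "n": len(vals)}
        for p, v in zip(PERCENTILES, np.percentile(vals, PERCENTILES)):
            row[f"p{p}"] = v
        pct_rows.append(row)

    contrast_rows = []
    for neg, pos in contrasts:
        batch = []
        for cid, sub in table.groupby("cluster_id"):
            a = sub.loc[sub["group"] == neg, "area_proportion"].to_numpy()
            b = sub.loc[sub["group"] == pos, "area_proportion"].to_numpy()
            if a.size < 2 or b.size < 2:
                continue
            tstat, pval = group_t_test(a, b)
            auc = marker_auc(
                np.concatenate([a, b]),
                np.concatenate([np.zeros(a.size, bool), np.ones(b.size, bool)]),
            )
            batch.append(
                {
                    "cluster_id": cid,
                    "negative": neg,
                    "positive": pos,
                    "t_statistic": tstat,
                    "p_value": pval,
                    "auc": auc,
                }
            )
        # raw p-values are primary; Holm adjustment (within contrast,
        # across clusters) is reported alongside
        for row, adj in zip(batch, holm_adjust([r["p_value"] for r in batch])):
            row["p_value_holm"] = adj
        contrast_rows.extend(batch)
    return pd.DataFrame(pct_rows), pd.DataFrame(contrast_rows)


def holm_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    if m == 0:
        return p
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj
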