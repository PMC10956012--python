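"""End-to-end orchestration: preprocess -> PBP -> super-pixel -> atlas -> markers.

The pipeline is driven by a strict, fully-seeded :class:`PipelineConfig`;
rerunning with the same config and inputs is bit-identical for every
deterministic stage.  :func:`analyze_images` is the in-memory entry point
used by the CLI, the tests and the refinement stage alike.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from . import io as pio
from .atlas import (
    AtlasModel,
    cluster_single_linkage,
    cut_largest_gap,
    fit_atlas,
    grid_trim,
    spread_labels,
)
from .markers import LabelMask, density_heatmap, marker_report, marker_table, project_labels_to_mask
from .mueller import MuellerImage, cloude_filter, gaussian_smooth, normalized_elements
from .pbp import ROTATION_STABLE_PBP_NAMES, pbp_image
from .superpixel import SuperPixelSet, build_superpixels, superpixel_pbp_means

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "AnalysisResult", "analyze_images", "run_pipeline", "refine_subclusters"]


@dataclass
class PipelineConfig:
    """All pipeline parameters; defaults mirror the study configuration."""

    manifest: str = ""
    out_dir: str = "polarmap_out"
    # preprocessing
    sigma_px: float = 1.0
    cloude: bool = True
    # polarization basis parameters
    pbp_selection: tuple[str, ...] = ROTATION_STABLE_PBP_NAMES
    # super-pixels
    superpixel_k: int = 1024
    superpixel_seed: int = 0
    batch_size: int = 4096
    n_init: int = 10
    max_iter: int = 300
    # atlas
    n_neighbors: int = 30
    metric: str = "canberra"
    min_dist: float = 0.1
    grid_nx: int = 200
    grid_ny: int = 200
    cutoff: int = 11
    n_clusters: Union[int, str] = "auto"  # "auto" = largest dendrogram gap
    max_clusters: int = 15
    spreading_k: int = 7
    atlas_seed: int = 0
    # markers
    contrasts: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if isinstance(self.n_clusters, str) and self.n_clusters != "auto":
            raise ValueError("n_clusters must be an integer or 'auto'")
        self.pbp_selection = tuple(self.pbp_selection)
        self.contrasts = tuple(tuple(c) for c in self.contrasts)

    @classmethod
    def desk_scale(cls, roi_pixels: int = 256 * 256, **overrides) -> "PipelineConfig":
        """Config scaled to desk-size ROIs while preserving study ratios.

        The study compresses ~1.3e6-pixel frames into 1024 super-pixels
        (~1.3e3 pixels each) and trims a ~2.3e5-point atlas on a 200x200
        grid with cutoff 11 (~5.7 points per occupied-core bin).  For
        smaller synthetic ROIs the super-pixel count and the trim grid
        are scaled to keep those densities comparable; the cutoff scales
        with expected bin occupancy.
        """
        k = max(16, int(round(roi_pixels / 1024)))
        cfg = dict(
            superpixel_k=k,
            grid_nx=25,
            grid_ny=25,
            cutoff=5,
        )
        cfg.update(overrides)
        return cls(**cfg)

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: Union[str, Path]) -> None:
        d = dataclasses.asdict(self)
        d["pbp_selection"] = list(d["pbp_selection"])
        d["contrasts"] = [list(c) for c in d["contrasts"]]
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    def param_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class AnalysisResult:
    """Everything the pipeline produces for one set of ROIs."""

    atlas: AtlasModel
    superpixels: dict[str, SuperPixelSet]
    roi_labels: dict[str, np.ndarray]  # per-ROI 0-based label per super-pixel
    masks: dict[str, LabelMask]
    table: pd.DataFrame
    metadata: dict[str, tuple[str, str, str]]  # roi_id -> (roi, patient, group)

    @property
    def cluster_ids(self) -> np.ndarray:
        """Mask/table cluster ids (1-based; 0 is reserved for unassigned)."""
        lab = self.atlas.labels
        return np.unique(lab[lab >= 0]) + 1


def preprocess(image: MuellerImage, cfg: PipelineConfig) -> MuellerImage:
    """Gaussian smoothing followed by physical (Cloude) filtering."""
    out = gaussian_smooth(image, cfg.sigma_px)
    if cfg.cloude:
        out = cloude_filter(out)
    return out


def compress_roi(
    image: MuellerImage, cfg: PipelineConfig, seed_offset: int = 0
) -> SuperPixelSet:
    """Preprocess one ROI and compress it into super-pixels with mean PBPs."""
    pre = preprocess(image, cfg)
    feats = normalized_elements(pre)
    pbp = pbp_image(pre, cfg.pbp_selection)
    # Pixels with undefined PBPs are excluded from the compression too, so
    # every super-pixel gets a finite mean PBP vector.
    feats.mask = feats.mask & pbp.mask
    sp = build_superpixels(
        feats,
        k=cfg.superpixel_k,
        seed=cfg.superpixel_seed + seed_offset,
        batch_size=cfg.batch_size,
        n_init=cfg.n_init,
        max_iter=cfg.max_iter,
    )
    return superpixel_pbp_means(sp, pbp)


def fit_and_cluster(
    rows: np.ndarray,
    source_keys: Sequence[tuple[str, int]],
    cfg: PipelineConfig,
) -> AtlasModel:
    """Embed pooled rows, trim, cluster, and spread labels to all points."""
    model = fit_atlas(
        rows,
        source_keys=source_keys,
        n_neighbors=cfg.n_neighbors,
        metric=cfg.metric,
        seed=cfg.atlas_seed,
        min_dist=cfg.min_dist,
    )
    retained, grid = grid_trim(model.embedding, cfg.grid_nx, cfg.grid_ny, cfg.cutoff)
    if not retained.any():
        logger.warning("density trim removed every point; retaining all")
        retained = np.ones(model.n_points, dtype=bool)
    model.retained_mask = retained
    model.density_grid = grid

    pts = model.embedding[retained]
    if pts.shape[0] == 1:
        cluster_labels = np.zeros(1, dtype=int)
        Z = np.empty((0, 4))
    else:
        from scipy.cluster.hierarchy import fcluster, linkage as _linkage

        Z = _linkage(pts, method="single")
        if cfg.n_clusters == "auto":
            n_clusters = cut_largest_gap(Z, cfg.max_clusters)
            logger.info("auto dendrogram cut chose %d clusters", n_clusters)
        else:
            n_clusters = int(cfg.n_clusters)
        raw = fcluster(Z, t=n_clusters, criterion="maxclust")
        _, cluster_labels = np.unique(raw, return_inverse=True)
    model.linkage_tree = Z

    labels = np.full(model.n_points, -1, dtype=int)
    labels[retained] = cluster_labels
    model.labels = spread_labels(model.embedding, labels, cfg.spreading_k)
    model.params.update(
        {
            "grid_nx": cfg.grid_nx,
            "grid_ny": cfg.grid_ny,
            "cutoff": cfg.cutoff,
            "n_clusters": int(n_clusters),
            "spreading_k": cfg.spreading_k,
        }
    )
    return model


def analyze_images(
    images: Sequence[MuellerImage],
    cfg: Optional[PipelineConfig] = None,
    precomputed_superpixels: Optional[Mapping[str, SuperPixelSet]] = None,
) -> AnalysisResult:
    """Run the full analysis on in-memory ROIs.

    Each ROI is preprocessed and compressed (super-pixel seeds offset by
    ROI position for independence), the pooled super-pixels are embedded
    and clustered, labels are projected back to pixel masks, and the
    cluster-area-proportion marker table is assembled.
    """
    cfg = cfg or PipelineConfig()
    if not images:
        raise ValueError("no ROIs to analyze")
    ids = [im.roi_id for im in images]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate roi_id among input images")

    superpixels: dict[str, SuperPixelSet] = {}
    for i, image in enumerate(images):
        if precomputed_superpixels and image.roi_id in precomputed_superpixels:
            superpixels[image.roi_id] = precomputed_superpixels[image.roi_id]
        else:
            logger.info("compressing ROI %s (%d/%d)", image.roi_id, i + 1, len(images))
            superpixels[image.roi_id] = compress_roi(image, cfg, seed_offset=i)

    rows_list, keys = [], []
    for roi_id in ids:
        sp = superpixels[roi_id]
        ok = np.isfinite(sp.mean_pbp).all(axis=1)
        for j in np.flatnonzero(ok):
            keys.append((roi_id, int(j)))
        rows_list.append(sp.mean_pbp[ok])
    rows = np.vstack(rows_list)

    model = fit_and_cluster(rows, keys, cfg)

    # Scatter atlas labels back to (roi, superpixel) and build masks.
    roi_labels = {roi_id: np.full(superpixels[roi_id].k, -1, dtype=int) for roi_id in ids}
    for (roi_id, j), lab in zip(model.source_keys, model.labels):
        roi_labels[roi_id][j] = lab

    metadata = {im.roi_id: (im.roi_id, im.patient_id, im.group) for im in images}
    masks = {
        roi_id: project_labels_to_mask(
            superpixels[roi_id], roi_labels[roi_id], allow_unassigned=True
        )
        for roi_id in ids
    }
    cluster_ids = np.unique(model.labels[model.labels >= 0]) + 1
    table = marker_table(
        [masks[r] for r in ids], [metadata[r] for r in ids], cluster_ids
    )
    return AnalysisResult(
        atlas=model,
        superpixels=superpixels,
        roi_labels=roi_labels,
        masks=masks,
        table=table,
        metadata=metadata,
    )


def _render_outputs(result: AnalysisResult, cfg: PipelineConfig, out_dir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy.cluster.hierarchy import dendrogram

    model = result.atlas
    if model.linkage_tree is not None and len(model.linkage_tree):
        fig, ax = plt.subplots(figsize=(6, 4))
        dendrogram(
            model.linkage_tree,
            ax=ax,
            truncate_mode="lastp",
            p=model.params.get("n_clusters", 6),
            orientation="right",
            no_labels=True,
        )
        ax.set_xlabel("merge distance")
        fig.savefig(out_dir / "dendrogram.svg", bbox_inches="tight")
        plt.close(fig)

    # Per-group log-density heatmaps on shared axes.
    if model.density_grid is not None:
        groups = sorted({meta[2] for meta in result.metadata.values()})
        roi_of_row = np.array([k[0] for k in model.source_keys])
        group_of_roi = {r: g for r, (_, _, g) in result.metadata.items()}
        row_groups = np.array([group_of_roi[r] for r in roi_of_row])
        for g in groups:
            sel = row_groups == g
            if not sel.any():
                continue
            grid, img = density_heatmap(model.embedding, sel, model.density_grid)
            np.savez(out_dir / f"heatmap_{g}.npz", counts=grid.counts, extent=grid.extent)
            fig, ax = plt.subplots(figsize=(4, 4))
            ax.imshow(img.T, origin="lower", extent=grid.extent, aspect="auto")
            ax.set_title(g)
            fig.savefig(out_dir / f"heatmap_{g}.png", dpi=120, bbox_inches="tight")
            plt.close(fig)


def run_pipeline(cfg: PipelineConfig) -> Path:
    """File-based pipeline entry: manifest in, artifact directory out."""
    manifest = pio.read_manifest(cfg.manifest)
    base = Path(cfg.manifest).parent
    images = []
    for _, row in manifest.iterrows():
        p = Path(row["path"])
        if not p.is_absolute():
            p = base / p
        if not p.exists():
            raise FileNotFoundError(f"ROI file missing: {p}")
        image = pio.load_mueller(p)
        images.append(
            replace(
                image,
                roi_id=row["roi_id"],
                patient_id=row["patient_id"],
                group=row["group"],
                mask=image.mask.copy(),
            )
        )

    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out_dir / "config.yaml")
    logger.info("pipeline start: %d ROIs, param hash %s", len(images), cfg.param_hash())

    result = analyze_images(images, cfg)

    sp_dir = out_dir / "superpixels"
    sp_dir.mkdir(exist_ok=True)
    for roi_id, sp in result.superpixels.items():
        pio.save_superpixels_npz(sp_dir / f"{roi_id}.npz", sp)
    mask_dir = out_dir / "masks"
    mask_dir.mkdir(exist_ok=True)
    for roi_id, mask in result.masks.items():
        pio.save_label_mask(mask_dir / f"{roi_id}.tiff", mask)
    pio.save_atlas(out_dir, result.atlas)
    result.table.to_csv(out_dir / "marker_table.csv", index=False)

    groups = sorted({m[2] for m in result.metadata.values()})
    contrasts = cfg.contrasts or tuple(
        (groups[i], groups[j]) for i in range(len(groups)) for j in range(i + 1, len(groups))
    )
    contrasts = tuple(c for c in contrasts if c[0] in groups and c[1] in groups)
    pct, tests = marker_report(result.table, groups, contrasts)
    pct.to_csv(out_dir / "marker_percentiles.csv", index=False)
    tests.to_csv(out_dir / "marker_tests.csv", index=False)
    _render_outputs(result, cfg, out_dir)
    logger.info("pipeline done: artifacts in %s", out_dir)
    return out_dir


def refine_subclusters(
    images: Sequence[MuellerImage],
    result: AnalysisResult,
    selected_clusters: Sequence[int],
    k_fine: int,
    cfg: Optional[PipelineConfig] = None,
    seed: int = 0,
) -> AnalysisResult:
    """Re-analyze the pixels of selected clusters at finer granularity.

    Pixels whose coarse mask label (1-based) is in ``selected_clusters``
    are re-compressed with ``k_fine`` super-pixels per ROI and re-embedded
    and re-clustered by the same pipeline.
    """
    selected = set(int(c) for c in selected_clusters)
    if not selected:
        raise ValueError("selection of clusters is empty")
    cfg = dataclasses.replace(
        cfg or PipelineConfig(),
        superpixel_k=k_fine,
        superpixel_seed=seed,
        atlas_seed=seed,
    )
    sub_images = []
    for image in images:
        mask = result.masks[image.roi_id].labels
        keep = np.isin(mask, list(selected)) & image.mask
        if keep.sum() == 0:
            logger.info("ROI %s has no pixels in the selection; skipped", image.roi_id)
            continue
        sub_images.append(replace(image, mask=keep))
    if not sub_images:
        raise ValueError("no pixels fall in the selected clusters")
    return analyze_images(sub_images, cfg)
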