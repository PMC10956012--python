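"""File dialects: Mueller NPZ / 16-page TIFF, manifests, model artifacts.

All dialects are documented and validated on read; write followed by read
is the identity on values and metadata within float32 precision.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import tifffile
import yaml

from .atlas import AtlasModel
from .markers import LabelMask
from .mueller import MuellerImage
from .pbp import PBPImage
from .superpixel import SuperPixelSet

__all__ = [
    "FormatError",
    "save_mueller_npz",
    "load_mueller_npz",
    "save_mueller_tiff",
    "load_mueller_tiff",
    "load_mueller",
    "read_manifest",
    "save_pbp_npz",
    "load_pbp_npz",
    "save_superpixels_npz",
    "load_superpixels_npz",
    "save_atlas",
    "save_label_mask",
    "load_label_mask",
]

PathLike = Union[str, Path]


class FormatError(ValueError):
    """A file violates one of the documented dialect rules."""


# -- Mueller NPZ dialect -----------------------------------------------------
# key "M": float32 (H, W, 4, 4); optional "mask": bool (H, W);
# metadata: "roi_id", "patient_id", "group" as 0-d string arrays.

def save_mueller_npz(path: PathLike, image: MuellerImage) -> None:
    np.savez(
        path,
        M=image.elements.astype(np.float32),
        mask=image.mask,
        roi_id=np.array(image.roi_id),
        patient_id=np.array(image.patient_id),
        group=np.array(image.group),
        pixel_size_um=np.array(image.pixel_size_um),
        wavelength_nm=np.array(image.wavelength_nm),
    )


def load_mueller_npz(path: PathLike) -> MuellerImage:
    with np.load(path, allow_pickle=False) as z:
        if "M" not in z:
            raise FormatError(f"{path}: missing key 'M'")
        M = z["M"]
        if M.ndim != 4 or M.shape[2:] != (4, 4):
            raise FormatError(f"{path}: 'M' must be (H, W, 4, 4), got {M.shape}")
        if M.dtype.kind != "f":
            raise FormatError(f"{path}: 'M' must be floating point, got {M.dtype}")
        kwargs = {}
        if "mask" in z:
            kwargs["mask"] = z["mask"].astype(bool)
        for key in ("roi_id", "patient_id", "group"):
            if key in z:
                kwargs[key] = str(z[key])
        for key in ("pixel_size_um", "wavelength_nm"):
            if key in z:
                kwargs[key] = float(z[key])
        return MuellerImage(elements=M.astype(float), **kwargs)


# -- 16-page TIFF dialect ----------------------------------------------------
# Pages in row-major element order m11..m44, single-channel float32;
# metadata in a sidecar YAML (<stem>.yaml next to the TIFF).

def save_mueller_tiff(path: PathLike, image: MuellerImage) -> None:
    path = Path(path)
    H, W = image.shape
    pages = image.elements.transpose(2, 3, 0, 1).reshape(16, H, W)
    tifffile.imwrite(path, pages.astype(np.float32))
    meta = {
        "roi_id": image.roi_id,
        "patient_id": image.patient_id,
        "group": image.group,
        "pixel_size_um": float(image.pixel_size_um),
        "wavelength_nm": float(image.wavelength_nm),
    }
    path.with_suffix(".yaml").write_text(yaml.safe_dump(meta))


def load_mueller_tiff(path: PathLike) -> MuellerImage:
    path = Path(path)
    pages = tifffile.imread(path)
    if pages.ndim != 3 or pages.shape[0] != 16:
        raise FormatError(
            f"{path}: expected 16 single-channel pages, got shape {pages.shape}"
        )
    if pages.dtype.kind != "f":
        raise FormatError(f"{path}: pages must be float32, got {pages.dtype}")
    H, W = pages.shape[1:]
    elements = pages.reshape(4, 4, H, W).transpose(2, 3, 0, 1).astype(float)
    kwargs = {}
    sidecar = path.with_suffix(".yaml")
    if sidecar.exists():
        meta = yaml.safe_load(sidecar.read_text()) or {}
        for key in ("roi_id", "patient_id", "group"):
            if key in meta:
                kwargs[key] = str(meta[key])
        for key in ("pixel_size_um", "wavelength_nm"):
            if key in meta:
                kwargs[key] = float(meta[key])
    return MuellerImage(elements=elements, **kwargs)


def load_mueller(path: PathLike) -> MuellerImage:
    """Dispatch on extension: .npz or .tif/.tiff."""
    path = Path(path)
    if path.suffix == ".npz":
        return load_mueller_npz(path)
    if path.suffix in (".tif", ".tiff"):
        return load_mueller_tiff(path)
    raise FormatError(f"{path}: unknown Mueller image extension {path.suffix!r}")


# -- Manifest CSV ------------------------------------------------------------

MANIFEST_COLUMNS = ("roi_id", "patient_id", "group", "path")


def read_manifest(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: manifest missing column(s) {missing}")
    if len(df) == 0:
        raise FormatError(f"{path}: no ROIs in manifest")
    if df["roi_id"].duplicated().any():
        raise FormatError(f"{path}: duplicate roi_id entries")
    return df


# -- PBP NPZ dialect ---------------------------------------------------------

def save_pbp_npz(path: PathLike, pbp: PBPImage) -> None:
    np.savez(
        path,
        pbp=pbp.values.astype(np.float32),
        names=np.array(pbp.names),
        mask=pbp.mask,
        roi_id=np.array(pbp.roi_id),
        provenance=np.array(json.dumps(pbp.provenance)),
    )


def load_pbp_npz(path: PathLike) -> PBPImage:
    with np.load(path, allow_pickle=False) as z:
        if "pbp" not in z or "names" not in z:
            raise FormatError(f"{path}: missing 'pbp' or 'names'")
        return PBPImage(
            values=z["pbp"].astype(float),
            names=tuple(str(n) for n in z["names"]),
            mask=z["mask"].astype(bool) if "mask" in z else None,
            roi_id=str(z["roi_id"]) if "roi_id" in z else "",
            provenance=json.loads(str(z["provenance"])) if "provenance" in z else {},
        )


# -- SuperPixelSet NPZ dialect ----------------------------------------------
# Member back-maps stored flat with offsets for text-free round-tripping.

def save_superpixels_npz(path: PathLike, sp: SuperPixelSet) -> None:
    flat = (
        np.concatenate(sp.member_index)
        if sp.k
        else np.empty((0, 2), dtype=np.int64)
    )
    offsets = np.concatenate([[0], np.cumsum(sp.counts)])
    np.savez(
        path,
        centroids=sp.centroids,
        counts=sp.counts,
        members_flat=flat.astype(np.int64),
        offsets=offsets.astype(np.int64),
        scaler_mean=sp.scaler_mean,
        scaler_scale=sp.scaler_scale,
        mean_pbp=sp.mean_pbp if sp.mean_pbp is not None else np.empty((0, 0)),
        pbp_names=np.array(sp.pbp_names, dtype=str),
        k=np.array(sp.k),
        seed=np.array(sp.seed),
        roi_id=np.array(sp.roi_id),
        image_shape=np.array(sp.image_shape),
    )


def load_superpixels_npz(path: PathLike) -> SuperPixelSet:
    with np.load(path, allow_pickle=False) as z:
        counts = z["counts"]
        offsets = z["offsets"]
        flat = z["members_flat"]
        members = [flat[offsets[i] : offsets[i + 1]] for i in range(len(counts))]
        mean_pbp = z["mean_pbp"]
        return SuperPixelSet(
            roi_id=str(z["roi_id"]),
            k=int(z["k"]),
            centroids=z["centroids"],
            member_index=members,
            counts=counts,
            scaler_mean=z["scaler_mean"],
            scaler_scale=z["scaler_scale"],
            seed=int(z["seed"]),
            image_shape=tuple(int(v) for v in z["image_shape"]),
            mean_pbp=mean_pbp if mean_pbp.size else None,
            pbp_names=tuple(str(n) for n in z["pbp_names"]),
        )


# -- Atlas artifacts ---------------------------------------------------------

def save_atlas(out_dir: PathLike, model: AtlasModel) -> None:
    """Persist embedding/labels/masks as NPZ + CSV and the linkage tree as CSV.

    The fitted projector itself is not serialized (opaque handle).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    np.savez(
        out_dir / "atlas.npz",
        embedding=model.embedding,
        retained_mask=(
            model.retained_mask
            if model.retained_mask is not None
            else np.zeros(0, bool)
        ),
        labels=model.labels if model.labels is not None else np.zeros(0, int),
        scaler_mean=model.scaler_mean,
        scaler_scale=model.scaler_scale,
    )
    rows = pd.DataFrame(
        {
            "roi_id": [k[0] for k in model.source_keys],
            "superpixel_index": [k[1] for k in model.source_keys],
            "x": model.embedding[:, 0],
            "y": model.embedding[:, 1],
            "retained": (
                model.retained_mask
                if model.retained_mask is not None
                else [True] * model.n_points
            ),
            "label": model.labels if model.labels is not None else -1,
        }
    )
    rows.to_csv(out_dir / "atlas_points.csv", index=False)
    if model.linkage_tree is not None and len(model.linkage_tree):
        pd.DataFrame(
            model.linkage_tree, columns=["node_a", "node_b", "distance", "size"]
        ).to_csv(out_dir / "linkage_tree.csv", index=False)
    (out_dir / "atlas_params.json").write_text(json.dumps(model.params, indent=2))


# -- Label masks -------------------------------------------------------------

def save_label_mask(path: PathLike, mask: LabelMask) -> None:
    lab = mask.labels
    if lab.max(initial=0) > 255:
        raise FormatError("label masks support at most 255 clusters (uint8)")
    tifffile.imwrite(Path(path), lab.astype(np.uint8))


def load_label_mask(path: PathLike, roi_id: str = "") -> LabelMask:
    lab = tifffile.imread(Path(path))
    if lab.ndim != 2:
        raise FormatError(f"{path}: label mask must be single-channel 2D")
    return LabelMask(labels=lab.astype(np.int32), roi_id=roi_id)
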