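# polarmap

Unsupervised tissue microstructural composition analysis of Mueller matrix
microscopy images.

A Mueller matrix image records, per pixel, the full 4×4 polarization
transfer matrix of a tissue section. `polarmap` compresses these pixels
into *polarization super-pixels*, embeds them into a shared 2D atlas,
clusters the atlas, projects the cluster labels back onto the image plane,
and quantifies *cluster area proportions* as candidate markers that track
pathology groups. A synthetic Mueller phantom generator with per-pixel
ground truth makes every stage testable without microscope data.

## Pipeline

1. **Preprocess** (`polarmap.mueller`) — per-plane Gaussian smoothing,
   then Cloude physical filtering: each pixel's coherency matrix is
   eigen-clamped so the Mueller matrix becomes physically realizable
   (total intensity preserved).
2. **Polarization basis parameters** (`polarmap.pbp`) — per pixel:
   Lu–Chipman polar-decomposition parameters (diattenuation D,
   depolarization Δ, retardances, orientations), Mueller-matrix
   transformation parameters (b, t1, A, α), and rotation-invariant
   element combinations. Extensible registry (`register_pbp`).
3. **Super-pixels** (`polarmap.superpixel`) — per ROI, minibatch k-means
   (default k = 1024) on the 15 m11-normalized Mueller elements after
   per-ROI standardization; records centroids, member-pixel back-maps,
   and mean PBP vectors.
4. **Atlas** (`polarmap.atlas`) — pooled super-pixels are globally
   standardized and embedded to 2D with UMAP (Canberra distance,
   30 neighbors), low-density grid bins are trimmed (200×200 grid,
   cutoff 11 by default), retained points are clustered by single
   linkage (cluster count fixed or chosen at the largest dendrogram
   gap), and trimmed points recover labels by k-NN label spreading.
   Stability diagnostics: convergence with training-data fraction and
   leave-one-patient-out projection distance.
5. **Markers** (`polarmap.markers`) — label masks, per-ROI cluster area
   proportions, Welch t-tests, rank-based AUC, box-whisker percentile
   reports (10/25/50/75/90), and log-density heatmaps on shared axes.
6. **Synthetic phantoms** (`polarmap.synthetic`) — canonical optical
   elements (depolarizer / retarder / rotator / diattenuator), spatially
   contiguous class regions with smooth parameter-field jitter, additive
   measurement noise, and ground-truth class maps. The default `liver6`
   preset has six classes spanning depolarization, retardance,
   anisotropy, orientation texture and diattenuation contrasts.
7. **Orchestration** (`polarmap.pipeline`, `polarmap.cli`) — YAML config
   with strict key validation, deterministic seeding per stage, and
   sub-cluster refinement of selected clusters at finer super-pixel
   granularity.

## CLI

```sh
# generate a phantom data set with a manifest
polarmap synth --preset liver6 --n-rois 20 --size 256 --seed 0 --out phantoms/

# run the full pipeline on a manifest
polarmap run --manifest phantoms/manifest.csv --out results/ --k 64

# or drive everything from a config file
polarmap run --config cfg.yaml
```

Per-stage subcommands (`preprocess`, `pbp`, `superpixel`, `convert`)
operate on single files in the documented NPZ/TIFF dialects. The output
directory contains the serialized config, per-ROI super-pixel sets and
label masks, the atlas (embedding + labels + linkage tree + dendrogram),
the marker table, and percentile/test reports as CSV.

### File dialects

- **Mueller NPZ**: key `M` float32 `(H, W, 4, 4)`, optional boolean
  `mask`, string keys `roi_id`, `patient_id`, `group`.
- **16-page TIFF**: float32 pages in row-major element order m11…m44,
  metadata in a sidecar YAML next to the file.
- **Manifest CSV**: columns `roi_id, patient_id, group, path`.

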