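"""Mueller matrix image data model, smoothing, physical filtering, normalization.

A Mueller matrix image is an H x W grid of real 4x4 matrices describing how
each sample point transforms Stokes vectors.  The matrix is physically
realizable iff its associated 4x4 Hermitian coherency matrix is positive
semi-definite; clamping negative coherency eigenvalues removes the
unphysical part of a measured matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

__all__ = [
    "MuellerImage",
    "FeatureImage",
    "FEATURE_NAMES",
    "mueller_to_coherency",
    "coherency_to_mueller",
    "gaussian_smooth",
    "cloude_filter",
    "normalized_elements",
]

# Pauli spin basis used for the Mueller <-> coherency linear bijection.
_PAULI = np.array(
    [
        [[1, 0], [0, 1]],
        [[1, 0], [0, -1]],
        [[0, 1], [1, 0]],
        [[0, -1j], [1j, 0]],
    ],
    dtype=complex,
)

# B[i, j] = sigma_i (x) sigma_j* ; orthogonal under the Hilbert-Schmidt
# inner product with tr(B_ij^H B_kl) = 4 delta_ik delta_jl.
_BASIS = np.array(
    [[np.kron(_PAULI[i], _PAULI[j].conj()) for j in range(4)] for i in range(4)]
)

#: Channel order of the 15 M11-normalized off-m11 elements (row-major).
FEATURE_NAMES = tuple(
    f"m{i + 1}{j + 1}/m11" for i in range(4) for j in range(4) if not (i == 0 and j == 0)
)
_FEATURE_IDX = [(i, j) for i in range(4) for j in range(4) if not (i == 0 and j == 0)]


@dataclass
class MuellerImage:
    """H x W grid of real 4x4 Mueller matrices plus acquisition metadata.

    ``mask`` marks valid pixels (True = valid); pixels with non-positive
    m11 are auto-masked at construction and excluded from all downstream
    stages.  Coordinates are 0-based (row, col), row-major.
    """

    elements: np.ndarray
    roi_id: str = ""
    patient_id: str = ""
    group: str = ""
    pixel_size_um: float = 1.0
    wavelength_nm: float = 633.0
    mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        el = np.asarray(self.elements, dtype=float)
        if el.ndim != 4 or el.shape[2:] != (4, 4):
            raise ValueError(f"elements must have shape (H, W, 4, 4), got {el.shape}")
        if el.shape[0] < 8 or el.shape[1] < 8:
            raise ValueError("Mueller images must be at least 8 x 8 pixels")
        if not np.isfinite(el).all():
            raise ValueError("Mueller elements must be finite everywhere")
        if self.pixel_size_um <= 0 or self.wavelength_nm <= 0:
            raise ValueError("pixel_size_um and wavelength_nm must be positive")
        self.elements = el
        if self.mask is None:
            self.mask = np.ones(el.shape[:2], dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != el.shape[:2]:
                raise ValueError("mask shape must match image shape")
        bad_m11 = self.mask & (el[..., 0, 0] <= 0)
        if bad_m11.any():
            logger.warning(
                "%s: masking %d pixel(s) with non-positive m11",
                self.roi_id or "<roi>",
                int(bad_m11.sum()),
            )
            self.mask = self.mask & ~bad_m11

    @property
    def shape(self) -> tuple[int, int]:
        return self.elements.shape[:2]

    @property
    def m11(self) -> np.ndarray:
        return self.elements[..., 0, 0]


@dataclass
class FeatureImage:
    """Per-pixel stack of the 15 M11-normalized Mueller elements."""

    features: np.ndarray  # (H, W, 15)
    feature_names: tuple[str, ...] = FEATURE_NAMES
    mask: Optional[np.ndarray] = None
    roi_id: str = ""

    def __post_init__(self) -> None:
        f = np.asarray(self.features, dtype=float)
        if f.ndim != 3 or f.shape[2] != len(self.feature_names):
            raise ValueError(
                f"features must have {len(self.feature_names)} channels, got {f.shape}"
            )
        self.features = f
        if self.mask is None:
            self.mask = np.ones(f.shape[:2], dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def shape(self) -> tuple[int, int]:
        return self.features.shape[:2]


def mueller_to_coherency(M: np.ndarray) -> np.ndarray:
    """Coherency matrix H = (1/4) sum_ij m_ij (sigma_i (x) sigma_j*).

    Accepts a single 4x4 matrix or any (..., 4, 4) stack.  H is Hermitian
    with trace(H) = m11, and the map is an exact linear bijection.
    """
    M = np.asarray(M, dtype=float)
    if M.shape[-2:] != (4, 4):
        raise ValueError("expected (..., 4, 4) array")
    if not np.isfinite(M).all():
        raise ValueError("Mueller matrix must be finite")
    return 0.25 * np.einsum("...ij,ijab->...ab", M, _BASIS)


def coherency_to_mueller(H: np.ndarray, *, herm_tol: float = 1e-8) -> np.ndarray:
    """Inverse of :func:`mueller_to_coherency` (exact linear inverse)."""
    H = np.asarray(H, dtype=complex)
    if H.shape[-2:] != (4, 4):
        raise ValueError("expected (..., 4, 4) array")
    scale = max(1.0, float(np.abs(H).max())) if H.size else 1.0
    if np.abs(H - np.conj(np.swapaxes(H, -1, -2))).max(initial=0.0) > herm_tol * scale:
        raise ValueError("coherency matrix is not Hermitian within tolerance")
    # Expansion coefficient in the orthogonal basis: m_ij = tr(H B_ij).
    M = np.einsum("...ab,ijba->...ij", H, _BASIS)
    return np.real(M)


def gaussian_smooth(image: MuellerImage, sigma_px: float = 1.0) -> MuellerImage:
    """Smooth each of the 16 element planes with an isotropic Gaussian.

    Borders are reflect-padded so constant images are preserved exactly
    and plane sums are conserved.  Metadata and mask are unchanged.
    """
    if sigma_px <= 0:
        raise ValueError("sigma_px must be positive")
    out = ndimage.gaussian_filter(
        image.elements, sigma=(sigma_px, sigma_px, 0, 0), mode="reflect"
    )
    return replace(image, elements=out, mask=image.mask.copy())


def _clamp_coherency(H: np.ndarray, m11: np.ndarray, eig_floor: float) -> np.ndarray:
    """Eigen-clamp a stack of coherency matrices and rescale trace to m11."""
    w, v = np.linalg.eigh(H)
    w = np.maximum(w, eig_floor)
    Hc = np.einsum("...ik,...k,...jk->...ij", v, w, np.conj(v))
    tr = np.real(np.trace(Hc, axis1=-2, axis2=-1))
    factor = np.where(tr > 0, m11 / np.where(tr > 0, tr, 1.0), 1.0)
    return Hc * factor[..., None, None]


def cloude_filter(image: MuellerImage, eig_floor: float = 0.0) -> MuellerImage:
    """Remove the physically unrealizable part of each pixel's Mueller matrix.

    Per valid pixel the coherency matrix is eigendecomposed, eigenvalues
    below ``eig_floor`` are clamped to it, the matrix is reconstructed with
    its trace rescaled to the original m11, and mapped back to Mueller
    form.  Already-physical pixels are returned bitwise unchanged, which
    also makes the filter exactly idempotent.
    """
    el = image.elements
    mask = image.mask
    out = el.copy()
    if mask.any():
        H = mueller_to_coherency(el[mask])
        w = np.linalg.eigvalsh(H)
        needs = w[:, 0] < eig_floor
        if needs.any():
            m11 = el[mask][needs, 0, 0]
            Hc = _clamp_coherency(H[needs], m11, eig_floor)
            fixed = coherency_to_mueller(Hc)
            tmp = out[mask]
            tmp[needs] = fixed
            out[mask] = tmp
    return replace(image, elements=out, mask=mask.copy())


def normalized_elements(image: MuellerImage) -> FeatureImage:
    """The 15 off-m11 elements divided by m11, in fixed row-major order.

    Pixels with non-positive m11 are masked (with a warning) rather than
    clipped; the result is invariant to any positive global gain.
    """
    el = image.elements
    m11 = el[..., 0, 0]
    mask = image.mask & (m11 > 0)
    n_new_bad = int((image.mask & ~mask).sum())
    if n_new_bad:
        logger.warning(
            "%s: masking %d pixel(s) with non-positive m11 during normalization",
            image.roi_id or "<roi>",
            n_new_bad,
        )
    safe_m11 = np.where(m11 > 0, m11, 1.0)
    feats = np.stack([el[..., i, j] / safe_m11 for i, j in _FEATURE_IDX], axis=-1)
    return FeatureImage(features=feats, mask=mask, roi_id=image.roi_id)
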