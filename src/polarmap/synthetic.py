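"""Mueller-matrix phantoms with known per-pixel class structure.

Canonical optical elements (depolarizer, retarder, rotator, diattenuator)
are composed per pixel from jittered class parameters over spatially
contiguous class regions, providing a fully controlled test surface for
the clustering pipeline: the ground-truth class map is carried alongside
the image.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
from scipy import ndimage

from .mueller import MuellerImage, coherency_to_mueller, mueller_to_coherency

__all__ = [
    "ClassSpec",
    "Phantom",
    "canonical_mueller",
    "rotate_mueller",
    "generate_phantom",
    "perturb_nonphysical",
    "liver6_classes",
]


def _rotation_matrix(theta: np.ndarray) -> np.ndarray:
    """4x4 Stokes rotation with cos/sin(2 theta) in the (Q, U) block."""
    theta = np.asarray(theta, dtype=float)
    c = np.cos(2 * theta)
    s = np.sin(2 * theta)
    R = np.zeros(theta.shape + (4, 4))
    R[..., 0, 0] = 1.0
    R[..., 1, 1] = c
    R[..., 1, 2] = -s
    R[..., 2, 1] = s
    R[..., 2, 2] = c
    R[..., 3, 3] = 1.0
    return R


def rotate_mueller(M: np.ndarray, theta: float | np.ndarray) -> np.ndarray:
    """In-plane sample rotation: R(theta) . M . R(-theta)."""
    M = np.asarray(M, dtype=float)
    R = _rotation_matrix(theta)
    Rm = _rotation_matrix(-np.asarray(theta, dtype=float))
    return R @ M @ Rm


def _depolarizer(a, b, c) -> np.ndarray:
    a, b, c = np.broadcast_arrays(
        np.asarray(a, float), np.asarray(b, float), np.asarray(c, float)
    )
    for v in (a, b, c):
        if ((v <= 0) | (v > 1)).any():
            raise ValueError("depolarizer diagonal must be in (0, 1]")
    M = np.zeros(a.shape + (4, 4))
    M[..., 0, 0] = 1.0
    M[..., 1, 1] = a
    M[..., 2, 2] = b
    M[..., 3, 3] = c
    return M


def _linear_retarder(delta, theta=0.0) -> np.ndarray:
    delta = np.asarray(delta, dtype=float)
    M = np.zeros(delta.shape + (4, 4))
    M[..., 0, 0] = 1.0
    M[..., 1, 1] = 1.0
    M[..., 2, 2] = np.cos(delta)
    M[..., 2, 3] = np.sin(delta)
    M[..., 3, 2] = -np.sin(delta)
    M[..., 3, 3] = np.cos(delta)
    theta = np.asarray(theta, dtype=float)
    if np.any(theta != 0):
        M = rotate_mueller(M, theta)
    return M


def _rotator(psi) -> np.ndarray:
    psi = np.asarray(psi, dtype=float)
    c = np.cos(2 * psi)
    s = np.sin(2 * psi)
    M = np.zeros(psi.shape + (4, 4))
    M[..., 0, 0] = 1.0
    M[..., 1, 1] = c
    M[..., 1, 2] = -s
    M[..., 2, 1] = s
    M[..., 2, 2] = c
    M[..., 3, 3] = 1.0
    return M


def _diattenuator(d, theta=0.0, transmittance=None) -> np.ndarray:
    d = np.asarray(d, dtype=float)
    if ((d < 0) | (d > 1)).any():
        raise ValueError("diattenuation must be in [0, 1]")
    if transmittance is None:
        # Peak transmittance 1: T_u (1 + D) = 1.
        transmittance = 1.0 / (1.0 + d)
    t = np.asarray(transmittance, dtype=float)
    q = np.sqrt(np.clip(1.0 - d**2, 0.0, None))
    M = np.zeros(np.broadcast(d, t).shape + (4, 4))
    M[..., 0, 0] = 1.0
    M[..., 0, 1] = d
    M[..., 1, 0] = d
    M[..., 1, 1] = 1.0
    M[..., 2, 2] = q
    M[..., 3, 3] = q
    M = M * t[..., None, None]
    theta = np.asarray(theta, dtype=float)
    if np.any(theta != 0):
        M = rotate_mueller(M, theta)
    return M


_KINDS = {
    "depolarizer": _depolarizer,
    "linear_retarder": _linear_retarder,
    "rotator": _rotator,
    "diattenuator": _diattenuator,
}


def canonical_mueller(kind: str, **params) -> np.ndarray:
    """Closed-form textbook Mueller matrix of a canonical element.

    kinds: ``depolarizer(a, b, c)`` -> diag(1, a, b, c);
    ``linear_retarder(delta, theta=0)``; ``rotator(psi)``;
    ``diattenuator(d, theta=0, transmittance=None)`` where the default
    transmittance 1/(1+d) yields the familiar 1/2-scaled ideal polarizer
    at d = 1.  Parameters may be arrays (broadcast to a matrix stack).
    """
    if kind not in _KINDS:
        raise ValueError(f"unknown element kind {kind!r}; known: {sorted(_KINDS)}")
    return _KINDS[kind](**params)


def perturb_nonphysical(M: np.ndarray, eps: float) -> np.ndarray:
    """Push the smallest coherency eigenvalue down by ``eps``.

    Produces a controlled physicality violation (fixture for the Cloude
    filter): the output's minimum coherency eigenvalue equals the
    original minimum minus eps.
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    H = mueller_to_coherency(M)
    w, v = np.linalg.eigh(H)
    vmin = v[..., :, 0]
    Hp = H - eps * (vmin[..., :, None] * np.conj(vmin[..., None, :]))
    return coherency_to_mueller(Hp)


@dataclass
class ClassSpec:
    """Generative recipe for one phantom tissue class.

    ``theta`` may be a number (radians) or the string ``"textured"``, in
    which case the orientation varies smoothly across the region so that
    orientation-sensitive raw elements vary while rotation-invariant
    parameters stay class-stable.
    """

    name: str
    depol: tuple[float, float, float] = (1.0, 1.0, 1.0)
    delta: float = 0.0
    theta: Union[float, str] = 0.0
    diatt: float = 0.0
    jitter_sd: Mapping[str, float] = field(default_factory=dict)
    abundance: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < min(self.depol) and max(self.depol) <= 1):
            raise ValueError(f"{self.name}: depol diagonal must be in (0, 1]")
        if not (0 <= self.diatt < 1):
            raise ValueError(f"{self.name}: diattenuation must be in [0, 1)")
        if self.abundance <= 0:
            raise ValueError(f"{self.name}: abundance must be positive")

    def jitter(self, key: str) -> float:
        return float(self.jitter_sd.get(key, 0.0))


@dataclass
class Phantom:
    """A synthetic ROI: Mueller image plus its ground-truth class map."""

    image: MuellerImage
    class_map: np.ndarray  # (H, W) int, class index per pixel
    class_names: tuple[str, ...]
    seed: int


def liver6_classes() -> list[ClassSpec]:
    """Default six-class phantom: two depolarizers differing in strength,
    two weak retarders differing in anisotropy, one strong retarder with
    orientation texture, and one diattenuating retarder."""
    j = {"depol": 0.045, "delta": 0.12, "theta": 0.12, "diatt": 0.015}
    return [
        ClassSpec("depol_low", (0.97, 0.96, 0.95), 0.05, 0.8, 0.01, j),
        ClassSpec("depol_high", (0.30, 0.26, 0.22), 0.05, 0.8, 0.01, j),
        ClassSpec("ret_weak_lowA", (0.88, 0.85, 0.80), 0.70, 1.1, 0.02, j),
        ClassSpec("ret_weak_highA", (0.62, 0.57, 0.46), 1.30, 2.0, 0.02, j),
        ClassSpec("ret_strong_textured", (0.92, 0.88, 0.84), 2.40, "textured", 0.03, j),
        ClassSpec("diatt_ret", (0.76, 0.71, 0.63), 1.80, 0.6, 0.45, j),
    ]


def _smooth_field(rng: np.random.Generator, shape, scale_px: float) -> np.ndarray:
    f = ndimage.gaussian_filter(rng.standard_normal(shape), scale_px, mode="wrap")
    sd = f.std()
    return f / sd if sd > 0 else f


def _class_map(
    rng: np.random.Generator,
    shape: tuple[int, int],
    weights: np.ndarray,
    blob_scale_px: float,
) -> np.ndarray:
    """Contiguous class regions whose areas approximate ``weights``.

    Per-class smoothed Gaussian fields are argmax-combined; additive
    biases are calibrated iteratively so realized frequencies track the
    requested abundances.
    """
    C = len(weights)
    fields = np.stack([_smooth_field(rng, shape, blob_scale_px) for _ in range(C)])
    bias = np.zeros(C)
    npix = shape[0] * shape[1]
    for _ in range(200):
        cm = np.argmax(fields + bias[:, None, None], axis=0)
        freq = np.bincount(cm.ravel(), minlength=C) / npix
        err = weights - freq
        if np.abs(err).max() < 0.002:
            break
        bias += 2.0 * err
    return cm


def generate_phantom(
    class_specs: Optional[Sequence[ClassSpec]] = None,
    height: int = 256,
    width: int = 256,
    blob_scale_px: float = 32.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    roi_id: str = "phantom",
    patient_id: str = "p0",
    group: str = "phantom",
) -> Phantom:
    """Generate a phantom ROI with contiguous class regions.

    Per pixel M = depolarizer . linear_retarder(delta, theta) .
    diattenuator(D, theta), with Gaussian parameter jitter per class and
    optional i.i.d. Gaussian noise on all 16 elements; m11 is
    renormalized to 1.  Deterministic given ``seed``.
    """
    if class_specs is None:
        class_specs = liver6_classes()
    if len(class_specs) < 2:
        raise ValueError("at least two classes required")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    weights = np.array([c.abundance for c in class_specs], dtype=float)
    if not np.isfinite(weights).all() or weights.sum() <= 0:
        raise ValueError("class abundances must be positive and finite")
    weights = weights / weights.sum()

    rng = np.random.default_rng(seed)
    shape = (height, width)
    cm = _class_map(rng, shape, weights, blob_scale_px)

    # Per-pixel generative parameters.  Jitter is a smooth spatial random
    # field per class (correlation length ~ half the blob scale) rather
    # than i.i.d. pixel noise: tissue properties vary continuously in
    # space, and this is what makes super-pixel means inherit the
    # variation instead of averaging it away.
    jitter_scale = max(2.0, blob_scale_px / 2.0)
    a = np.empty(shape)
    b = np.empty(shape)
    c_ = np.empty(shape)
    delta = np.empty(shape)
    theta = np.empty(shape)
    diatt = np.empty(shape)
    texture = None
    for ci, spec in enumerate(class_specs):
        sel = cm == ci
        jd = spec.jitter("depol")
        # Jitter the depolarization diagonal by a common factor: independent
        # per-channel jitter can violate the Cloude physicality conditions
        # (e.g. 1 - a - b + c >= 0), a shared scale cannot once capped.
        a0, b0, c0 = spec.depol
        s_max = 1.0 / max(a0 + b0 - c0, a0 - b0 + c0, -a0 + b0 + c0, 1e-6)
        s_field = 1.0 + jd * _smooth_field(rng, shape, jitter_scale)
        s = np.clip(s_field[sel], 0.05, min(s_max, 1.0 / max(a0, b0, c0)))
        a[sel] = a0 * s
        b[sel] = b0 * s
        c_[sel] = c0 * s
        delta_field = spec.delta + spec.jitter("delta") * _smooth_field(
            rng, shape, jitter_scale
        )
        delta[sel] = np.clip(delta_field[sel], 0.0, np.pi - 1e-3)
        diatt_field = spec.diatt + spec.jitter("diatt") * _smooth_field(
            rng, shape, jitter_scale
        )
        diatt[sel] = np.clip(diatt_field[sel], 0.0, 0.95)
        if spec.theta == "textured":
            if texture is None:
                texture = _smooth_field(rng, shape, blob_scale_px)
                lo, hi = texture.min(), texture.max()
                texture = (texture - lo) / (hi - lo + 1e-12) * np.pi
            theta[sel] = texture[sel]
        else:
            theta_field = float(spec.theta) + spec.jitter("theta") * _smooth_field(
                rng, shape, jitter_scale
            )
            theta[sel] = np.mod(theta_field[sel], np.pi)

    M = (
        _depolarizer(a, b, c_)
        @ _linear_retarder(delta, theta)
        @ _diattenuator(diatt, theta)
    )
    if noise_sd > 0:
        M = M + rng.normal(0.0, noise_sd, M.shape)
    m11 = M[..., 0, 0]
    valid = m11 > 0
    M = M / np.where(valid, m11, 1.0)[..., None, None]

    image = MuellerImage(
        elements=M,
        roi_id=roi_id,
        patient_id=patient_id,
        group=group,
        mask=valid,
    )
    return Phantom(
        image=image,
        class_map=cm,
        class_names=tuple(s.name for s in class_specs),
        seed=seed,
    )
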