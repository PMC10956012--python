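"""Polarization basis parameters (PBPs) computed per pixel from Mueller matrices.

Three families are implemented:

* ``mmpd`` — polar-decomposition parameters from the product factorization
  M = M_delta . M_R . M_D (depolarizer, retarder, diattenuator):
  diattenuation D, depolarization Delta, total/linear retardance, optical
  rotation and fast-axis orientation.
* ``mmt`` — orientation-insensitive transformation parameters (b, t1, A,
  alpha) built from the central 2x2 block.
* ``rotation_invariants`` — norms of row/column element pairs that are
  unchanged under in-plane sample rotation.

All functions accept a single 4x4 matrix or an arbitrary (..., 4, 4)
stack and are vectorized; parameters that become undefined (ideal
diattenuation, full depolarization) are returned as NaN rather than
raising.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .mueller import MuellerImage

logger = logging.getLogger(__name__)

__all__ = [
    "MMPDParams",
    "MMTParams",
    "PBPImage",
    "mmpd",
    "mmt",
    "rotation_invariants",
    "pbp_image",
    "register_pbp",
    "available_pbp_names",
    "DEFAULT_PBP_NAMES",
]

_D_SATURATION = 1.0 - 1e-9


@dataclass(frozen=True)
class MMPDParams:
    """Scalar polar-decomposition parameters for one Mueller matrix."""

    D: float
    Delta: float
    R_tot: float
    delta_lin: float
    psi: float
    theta: float


@dataclass(frozen=True)
class MMTParams:
    """Scalar transformation parameters for one Mueller matrix."""

    b: float
    t1: float
    A: float
    alpha: float


def _as_batch(M: np.ndarray) -> tuple[np.ndarray, tuple[int, ...]]:
    M = np.asarray(M, dtype=float)
    if M.shape[-2:] != (4, 4):
        raise ValueError("expected (..., 4, 4) array")
    shape = M.shape[:-2]
    return M.reshape(-1, 4, 4), shape


def _mmpd_arrays(M: np.ndarray) -> dict[str, np.ndarray]:
    """Vectorized polar decomposition; returns flat arrays per parameter."""
    n = M.shape[0]
    out = {
        k: np.full(n, np.nan)
        for k in ("D", "Delta", "R_tot", "delta_lin", "psi", "theta")
    }
    m11 = M[:, 0, 0]
    ok = m11 > 0
    if not ok.any():
        return out
    Mn = M[ok] / m11[ok, None, None]

    dvec = Mn[:, 0, 1:4]
    D = np.linalg.norm(dvec, axis=1)
    out["D"][ok] = np.minimum(D, 1.0)

    # The retarder/depolarizer split needs M_D to be invertible.
    inv_ok = D < _D_SATURATION
    if not inv_ok.any():
        return out
    Mn = Mn[inv_ok]
    dvec = dvec[inv_ok]
    D = D[inv_ok]

    # M_D = [[1, d^T], [d, sqrt(1-D^2) I + (1 - sqrt(1-D^2)) dhat dhat^T]]
    q = np.sqrt(1.0 - D**2)
    with np.errstate(invalid="ignore", divide="ignore"):
        dhat = np.where(D[:, None] > 0, dvec / np.where(D[:, None] > 0, D[:, None], 1.0), 0.0)
    MD = np.zeros_like(Mn)
    MD[:, 0, 0] = 1.0
    MD[:, 0, 1:] = dvec
    MD[:, 1:, 0] = dvec
    MD[:, 1:, 1:] = q[:, None, None] * np.eye(3) + (1.0 - q)[:, None, None] * (
        dhat[:, :, None] * dhat[:, None, :]
    )
    Mp = Mn @ np.linalg.inv(MD)
    mp = Mp[:, 1:, 1:]

    # m_delta from the symmetric square-root prescription, sign by det(m').
    mmT = mp @ np.swapaxes(mp, 1, 2)
    lam = np.clip(np.linalg.eigvalsh(mmT), 0.0, None)
    s1, s2, s3 = np.sqrt(lam[:, 0]), np.sqrt(lam[:, 1]), np.sqrt(lam[:, 2])
    e1 = s1 + s2 + s3
    e2 = s1 * s2 + s2 * s3 + s3 * s1
    e3 = s1 * s2 * s3
    sign = np.where(np.linalg.det(mp) < 0, -1.0, 1.0)
    lhs = mmT + e2[:, None, None] * np.eye(3)
    rhs = e1[:, None, None] * mmT + e3[:, None, None] * np.eye(3)
    m_delta = sign[:, None, None] * np.linalg.solve(lhs, rhs)

    Delta = 1.0 - np.abs(np.trace(m_delta, axis1=1, axis2=2)) / 3.0
    idx = np.flatnonzero(ok)[inv_ok]
    out["Delta"][idx] = np.clip(Delta, 0.0, 1.0)

    # Retarder block m_R = m_delta^{-1} m'; undefined at full depolarization.
    det_mdelta = np.linalg.det(m_delta)
    ret_ok = np.abs(det_mdelta) > 1e-12
    if not ret_ok.any():
        return out
    mR = np.linalg.solve(m_delta[ret_ok], mp[ret_ok])
    idx = idx[ret_ok]

    tr_MR = 1.0 + np.trace(mR, axis1=1, axis2=2)
    arg = tr_MR / 2.0 - 1.0
    n_clip = int((np.abs(arg) > 1.0 + 1e-9).sum())
    if n_clip:
        logger.debug("mmpd: clipping %d retardance arccos argument(s)", n_clip)
    out["R_tot"][idx] = np.arccos(np.clip(arg, -1.0, 1.0))

    a = mR[:, 0, 0] + mR[:, 1, 1]
    bq = mR[:, 1, 0] - mR[:, 0, 1]
    out["delta_lin"][idx] = np.arccos(np.clip(np.sqrt(a**2 + bq**2) - 1.0, -1.0, 1.0))
    out["psi"][idx] = 0.5 * np.arctan2(bq, a)

    # Fast-axis orientation from the retardance (axial) vector of m_R.
    r1 = mR[:, 1, 2] - mR[:, 2, 1]
    r2 = mR[:, 2, 0] - mR[:, 0, 2]
    out["theta"][idx] = np.mod(0.5 * np.arctan2(r2, r1), np.pi)
    return out


def mmpd(M: np.ndarray) -> MMPDParams | dict[str, np.ndarray]:
    """Lu–Chipman polar-decomposition parameters.

    For a single 4x4 matrix returns :class:`MMPDParams`; for a stack
    returns a dict of arrays with the leading shape of the stack.
    Matrices with D at saturation (>= 1 - 1e-9) report D = 1 and NaN for
    the depolarization/retardance parameters instead of raising.
    """
    flat, shape = _as_batch(M)
    res = _mmpd_arrays(flat)
    if shape == ():
        return MMPDParams(**{k: float(v[0]) for k, v in res.items()})
    return {k: v.reshape(shape) for k, v in res.items()}


def _mmt_arrays(M: np.ndarray) -> dict[str, np.ndarray]:
    m11 = M[:, 0, 0]
    safe = np.where(m11 != 0, m11, 1.0)
    m22 = M[:, 1, 1] / safe
    m33 = M[:, 2, 2] / safe
    m23 = M[:, 1, 2] / safe
    m32 = M[:, 2, 1] / safe
    b = (m22 + m33) / 2.0
    t1 = 0.5 * np.sqrt((m22 - m33) ** 2 + (m23 + m32) ** 2)
    denom = b**2 + t1**2
    with np.errstate(invalid="ignore", divide="ignore"):
        A = np.where(denom > 0, 2.0 * b * t1 / np.where(denom > 0, denom, 1.0), 0.0)
    alpha = np.mod(0.25 * np.arctan2(m23 + m32, m22 - m33), np.pi)
    return {"b": b, "t1": t1, "A": np.clip(np.abs(A), 0.0, 1.0), "alpha": alpha}


def mmt(M: np.ndarray) -> MMTParams | dict[str, np.ndarray]:
    """Transformation parameters b, t1, A, alpha (m11-normalized elements).

    b = (m22 + m33)/2, t1 = sqrt((m22 - m33)^2 + (m23 + m32)^2)/2,
    A = 2 b t1 / (b^2 + t1^2) (0 when b = t1 = 0),
    alpha = atan2(m23 + m32, m22 - m33)/4 reported mod pi.  Note alpha has
    intrinsic period pi/2: a sample rotation by theta shifts it by theta
    modulo pi/2.
    """
    flat, shape = _as_batch(M)
    if not np.isfinite(flat).all():
        raise ValueError("Mueller matrix must be finite")
    res = _mmt_arrays(flat)
    if shape == ():
        return MMTParams(**{k: float(v[0]) for k, v in res.items()})
    return {k: v.reshape(shape) for k, v in res.items()}


def _rotation_invariant_arrays(M: np.ndarray) -> dict[str, np.ndarray]:
    m11 = M[:, 0, 0]
    safe = np.where(m11 > 0, m11, np.nan)
    return {
        "D_L": np.hypot(M[:, 0, 1], M[:, 0, 2]) / safe,
        "P_L": np.hypot(M[:, 1, 0], M[:, 2, 0]) / safe,
        "r_L": np.hypot(M[:, 1, 3], M[:, 2, 3]) / safe,
        "q_L": np.hypot(M[:, 3, 1], M[:, 3, 2]) / safe,
        "m44_n": M[:, 3, 3] / safe,
    }


def rotation_invariants(M: np.ndarray) -> dict[str, np.ndarray | float]:
    """Element combinations unchanged under in-plane sample rotation.

    D_L = |(m12, m13)|/m11, P_L = |(m21, m31)|/m11, r_L = |(m24, m34)|/m11,
    q_L = |(m42, m43)|/m11, plus m44/m11.
    """
    flat, shape = _as_batch(M)
    res = _rotation_invariant_arrays(flat)
    if shape == ():
        return {k: float(v[0]) for k, v in res.items()}
    return {k: v.reshape(shape) for k, v in res.items()}


# ---------------------------------------------------------------------------
# Registry: name -> (group computer, provenance id).  Each group computer
# maps a flat (n, 4, 4) stack to a dict of flat arrays.

_GROUPS: dict[str, Callable[[np.ndarray], dict[str, np.ndarray]]] = {
    "mmpd": _mmpd_arrays,
    "mmt": _mmt_arrays,
    "invariants": _rotation_invariant_arrays,
}

_REGISTRY: dict[str, tuple[str, str]] = {}  # name -> (group, provenance)
for _name in ("D", "Delta", "R_tot", "delta_lin", "psi", "theta"):
    _REGISTRY[_name] = ("mmpd", f"mmpd.{_name}")
for _name in ("b", "t1", "A", "alpha"):
    _REGISTRY[_name] = ("mmt", f"mmt.{_name}")
for _name in ("D_L", "P_L", "r_L", "q_L", "m44_n"):
    _REGISTRY[_name] = ("invariants", f"invariants.{_name}")

#: Default parameter set: polar decomposition + transformation + invariants.
DEFAULT_PBP_NAMES = (
    "D", "Delta", "R_tot", "delta_lin", "psi", "theta",
    "b", "t1", "A", "alpha",
    "D_L", "P_L", "r_L", "q_L", "m44_n",
)

#: Default set minus the orientation angles (sample-rotation dependent,
#: wrap mod pi) and the optical rotation psi (whose sign is numerically
#: undefined for near-isotropic retarder blocks and therefore bimodal
#: noise on depolarizing pixels); the pipeline embeds these by default.
ROTATION_STABLE_PBP_NAMES = tuple(
    n for n in DEFAULT_PBP_NAMES if n not in ("theta", "alpha", "psi")
)


def available_pbp_names() -> tuple[str, ...]:
    return tuple(_REGISTRY)


def register_pbp(
    name: str,
    func: Callable[[np.ndarray], np.ndarray],
    provenance: str = "custom",
) -> None:
    """Plug an additional scalar parameter into the registry.

    ``func`` receives a flat (n, 4, 4) stack and must return a flat (n,)
    array.
    """
    if name in _REGISTRY:
        raise ValueError(f"PBP {name!r} already registered")
    group_key = f"custom:{name}"
    _GROUPS[group_key] = lambda M, _f=func, _n=name: {_n: np.asarray(_f(M), dtype=float)}
    _REGISTRY[name] = (group_key, provenance)


@dataclass
class PBPImage:
    """H x W x P stack of named polarization basis parameters."""

    values: np.ndarray
    names: tuple[str, ...]
    provenance: dict[str, str] = field(default_factory=dict)
    mask: Optional[np.ndarray] = None
    roi_id: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 3 or v.shape[2] != len(self.names):
            raise ValueError("values must have one channel per name")
        if len(self.names) < 1:
            raise ValueError("at least one parameter required")
        self.values = v
        if self.mask is None:
            self.mask = np.ones(v.shape[:2], dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape[:2]


def pbp_image(
    image: MuellerImage, selection: Sequence[str] = DEFAULT_PBP_NAMES
) -> PBPImage:
    """Per-pixel PBP stack, channels in ``selection`` order.

    Masked pixels propagate; pixels where a parameter is undefined are
    additionally masked out.
    """
    selection = tuple(selection)
    if not selection:
        raise ValueError("selection must be non-empty")
    if len(set(selection)) != len(selection):
        raise ValueError("selection contains duplicate names")
    unknown = [n for n in selection if n not in _REGISTRY]
    if unknown:
        raise ValueError(
            f"unknown PBP name(s) {unknown}; known: {sorted(_REGISTRY)}"
        )

    H, W = image.shape
    mask = image.mask.copy()
    flat = image.elements[mask]
    values = np.full((H, W, len(selection)), np.nan)

    needed_groups = {_REGISTRY[n][0] for n in selection}
    computed: dict[str, np.ndarray] = {}
    for g in needed_groups:
        computed.update(_GROUPS[g](flat))

    for c, name in enumerate(selection):
        plane = np.full((H, W), np.nan)
        plane[mask] = computed[name]
        values[..., c] = plane

    finite = np.isfinite(values).all(axis=-1)
    out_mask = mask & finite
    n_dropped = int((mask & ~finite).sum())
    if n_dropped:
        logger.warning(
            "%s: masking %d pixel(s) with undefined PBP values",
            image.roi_id or "<roi>",
            n_dropped,
        )
    return PBPImage(
        values=values,
        names=selection,
        provenance={n: _REGISTRY[n][1] for n in selection},
        mask=out_mask,
        roi_id=image.roi_id,
    )
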