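"""Soma-to-terminal topography: medoids, least-squares fit, rotation.

The topographic map from a nucleus to its cortical targets is
quantified by (1) summarizing each neuron's axonal terminals by their
*medoid* — the member point minimizing total distance to the rest, so
the summary is always an actual termination location — then (2) fitting
an affine least-squares transform from soma positions to medoids,
(3) extracting the rotational part of the linear map by polar
decomposition A = R·S (R proper-orthogonal, S symmetric) and
(4) reporting R as Euler angles plus the fit's mean squared residual.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

#: the 12 proper Euler/Tait-Bryan axis sequences (lowercase = extrinsic)
EULER_CONVENTIONS = ("xyz", "xzy", "yxz", "yzx", "zxy", "zyx",
                     "XYZ", "XZY", "YXZ", "YZX", "ZXY", "ZYX")

DEFAULT_CONVENTION = "xyz"  # extrinsic X-then-Y-then-Z


class FitError(ValueError):
    """Degenerate least-squares problem (too few or coplanar somata)."""


@dataclass
class TopographyFit:
    linear: np.ndarray              # (3, 3)
    translation: np.ndarray         # (3,)
    rotation: np.ndarray            # (3, 3), proper rotation from polar decomp
    euler_deg: np.ndarray           # (3,), degrees, in `convention`
    mse: float                      # mean squared residual, unit²
    medoids: np.ndarray             # (n, 3), μm
    unit_um: float                  # coordinate unit of the fit (μm per unit)
    convention: str = DEFAULT_CONVENTION
    gimbal_lock: bool = False


def terminal_medoid(points) -> np.ndarray:
    """The member of a point set minimizing the summed Euclidean distance
    to all members (lowest index on ties)."""
    pts = np.asarray(points, float).reshape(-1, 3)
    if len(pts) == 0:
        raise ValueError("empty point set has no medoid")
    d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
    return pts[int(np.argmin(d.sum(axis=1)))]


def proper_polar_rotation(A: np.ndarray) -> np.ndarray:
    """Rotation factor of the polar decomposition A = R·S with a
    determinant correction forcing det R = +1."""
    U, _s, Vt = np.linalg.svd(np.asarray(A, float))
    C = np.diag([1.0, 1.0, np.sign(np.linalg.det(U @ Vt))])
    return U @ C @ Vt


def euler_from_rotation(R: np.ndarray, convention: str = DEFAULT_CONVENTION
                        ) -> tuple[np.ndarray, bool]:
    """Euler angles (degrees) of a proper rotation.

    Returns ``(angles, gimbal_lock)``; at gimbal lock the third angle is
    zeroed (the first absorbs the full in-plane rotation) and the flag
    set.
    """
    R = np.asarray(R, float)
    if not np.allclose(R.T @ R, np.eye(3), atol=1e-6) or np.linalg.det(R) < 0:
        raise ValueError("input is not a proper rotation matrix")
    import warnings as _w
    with _w.catch_warnings(record=True) as caught:
        _w.simplefilter("always")
        angles = Rotation.from_matrix(R).as_euler(convention, degrees=True)
        lock = any("Gimbal lock" in str(c.message) for c in caught)
    return angles, lock


def fit_topography(somata, medoids, unit_um: float = 10.0,
                   convention: str = DEFAULT_CONVENTION) -> TopographyFit:
    """Affine least-squares fit soma -> terminal medoid.

    Inputs are in μm; the fit is performed after rescaling both point
    sets to ``unit_um``-sized units (default 10-μm voxels), which sets
    the unit of the reported MSE.  The rotation is read from the linear
    part only.
    """
    S = np.asarray(somata, float).reshape(-1, 3) / unit_um
    T = np.asarray(medoids, float).reshape(-1, 3) / unit_um
    if len(S) != len(T):
        raise FitError("somata and medoids must pair up")
    if len(S) < 4:
        raise FitError("need at least 4 soma/medoid pairs")
    X = np.hstack([S, np.ones((len(S), 1))])          # homogeneous design
    if np.linalg.matrix_rank(X) < 4:
        raise FitError("degenerate fit: somata are coplanar or coincident")
    coef, *_ = np.linalg.lstsq(X, T, rcond=None)       # (4, 3)
    A = coef[:3, :].T                                  # so that T ≈ A S + t
    t = coef[3, :]
    R = proper_polar_rotation(A)
    angles, lock = euler_from_rotation(R, convention)
    resid = T - (S @ A.T + t)
    mse = float((resid ** 2).sum(axis=1).mean())
    return TopographyFit(linear=A, translation=t, rotation=R,
                         euler_deg=angles, mse=mse,
                         medoids=np.asarray(medoids, float).reshape(-1, 3),
                         unit_um=unit_um, convention=convention,
                         gimbal_lock=lock)


def rotation_geodesic_deg(R1: np.ndarray, R2: np.ndarray) -> float:
    """Geodesic angle (degrees) between two rotations."""
    R = np.asarray(R1) @ np.asarray(R2).T
    cos = np.clip((np.trace(R) - 1.0) / 2.0, -1.0, 1.0)
    return float(np.degrees(np.arccos(cos)))


def best_convention_match(R: np.ndarray, target_deg) -> tuple[str, np.ndarray, float]:
    """Search the 12 Euler conventions for the one whose angles best match
    ``target_deg`` (max absolute angle difference); used when comparing
    against reported angles of unknown convention."""
    target = np.asarray(target_deg, float)
    best = None
    for conv in EULER_CONVENTIONS:
        ang, _lock = euler_from_rotation(R, conv)
        err = float(np.max(np.abs(ang - target)))
        if best is None or err < best[2]:
            best = (conv, ang, err)
    return best
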