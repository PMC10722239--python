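"""Rotation-only rigid Coherent Point Drift and pairwise dissimilarities.

Coherent Point Drift (CPD) treats the moving point cloud as the
centroids of an isotropic Gaussian mixture and fits it to the reference
cloud by expectation-maximization, estimating the transformation and
the mixture variance σ² jointly.  Here the transformation is restricted
to a proper rotation about the origin: both clouds are soma-centered, so
eliminating translation and scaling makes the final registration error a
pure measure of difference in axonal branching pattern, invariant to
soma location and to rotation of either neuron.

The E-step computes responsibilities

    P[m, n] = exp(-|x_n - R y_m|² / 2σ²) / (Σ_k exp(-|x_n - R y_k|² / 2σ²) + c)

with the uniform-outlier constant c = (2πσ²)^{3/2} w M / ((1-w) N); the
M-step takes R from the SVD of the posterior-weighted cross-covariance
A = Σ_{mn} P[m,n] x_n y_mᵀ with a determinant correction that forbids
reflections, and updates σ² by the standard rigid formula.  Iteration
stops when the negative log-likelihood changes by less than ``tol`` or
after ``max_iter`` rounds.  The reported MSE uses hard correspondences:
each moving point is paired with its argmax-responsibility reference
point.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .tree import TopologicalMinor

log = logging.getLogger(__name__)

_D = 3  # ambient dimension


class AlignmentError(ValueError):
    """Degenerate input to the registration (too few or collinear points)."""


@dataclass(frozen=True)
class CPDConfig:
    """Settings for rotation-only rigid CPD.

    ``max_iter``/``tol`` default to the strictest values that keep a
    ~400-point pair under interactive runtimes; ``w`` is the uniform
    outlier weight (0 disables the outlier term); ``max_points``
    subsamples larger clouds (deterministically, per ``seed``).
    """

    max_iter: int = 60
    tol: float = 1e-3
    w: float = 0.0
    allow_scale: bool = False       # fixed: scaling is excluded by design
    allow_translation: bool = False  # fixed: inputs are soma-centered
    max_points: int | None = None
    seed: int = 0
    soft_mse: bool = False          # responsibility-weighted MSE variant

    def __post_init__(self) -> None:
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if not (0.0 <= self.w < 1.0):
            raise ValueError("w must lie in [0, 1)")
        if self.allow_scale or self.allow_translation:
            raise ValueError("scale/translation registration is not supported")


@dataclass
class CPDResult:
    rotation: np.ndarray            # (3, 3), proper rotation
    sigma2: float                   # final mixture variance, μm²
    n_iter: int
    converged_by: str               # "tol" | "max_iter"
    correspondence: np.ndarray      # moving index -> reference index
    mse: float                      # μm²
    objective: float                # final negative log-likelihood


def _check_cloud(pts: np.ndarray, name: str) -> np.ndarray:
    pts = np.asarray(pts, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != _D:
        raise AlignmentError(f"{name} cloud must be (n, 3)")
    if len(pts) < 3:
        raise AlignmentError(f"{name} cloud needs >= 3 points")
    if np.linalg.matrix_rank(pts - pts.mean(axis=0)) < 2:
        raise AlignmentError(f"{name} cloud is rank-deficient (collinear)")
    return pts


def _subsample(pts: np.ndarray, cap: int | None, rng: np.random.Generator) -> np.ndarray:
    if cap is None or len(pts) <= cap:
        return pts
    idx = rng.choice(len(pts), size=cap, replace=False)
    return pts[np.sort(idx)]


def e_step(moving: np.ndarray, reference: np.ndarray, rotation: np.ndarray,
           sigma2: float, w: float = 0.0) -> tuple[np.ndarray, float]:
    """One CPD E-step: responsibilities P (M×N) and the negative
    log-likelihood of the reference under the current mixture."""
    X, Y = reference, moving @ rotation.T
    M, N = len(Y), len(X)
    d2 = ((X[None, :, :] - Y[:, None, :]) ** 2).sum(axis=-1)      # (M, N)
    K = np.exp(-d2 / (2.0 * sigma2))
    c = (2.0 * np.pi * sigma2) ** (_D / 2.0) * w * M / ((1.0 - w) * N)
    denom = K.sum(axis=0) + c
    denom = np.where(denom > 0, denom, np.finfo(float).tiny)
    P = K / denom[None, :]
    # NLL of the data: -Σ_n log( (1-w)/M (2πσ²)^{-3/2} Σ_m K + w/N )
    mix = (1.0 - w) / M * (2.0 * np.pi * sigma2) ** (-_D / 2.0) * K.sum(axis=0) \
        + w / N
    mix = np.where(mix > 0, mix, np.finfo(float).tiny)
    nll = float(-np.log(mix).sum())
    return P, nll


def cpd_rigid_rotation(moving, reference, cfg: CPDConfig = CPDConfig()) -> CPDResult:
    """Register ``moving`` onto ``reference`` by a rotation about the origin.

    Both clouds must already be soma-centered (mean position may be
    nonzero, but the soma sits at the origin); a cloud whose centroid is
    far outside its own extent is rejected as likely non-centered.
    """
    X = _check_cloud(reference, "reference")
    Y = _check_cloud(moving, "moving")
    for pts, name in ((X, "reference"), (Y, "moving")):
        centroid = pts.mean(axis=0)
        radius = np.linalg.norm(pts - centroid, axis=1).max()
        if np.linalg.norm(centroid) > radius * (1.0 + 1e-9):
            # origin outside the cloud's circumscribed ball (a soma-centered
            # cloud contains the origin as a member): not soma-centered
            raise AlignmentError(f"{name} cloud does not appear soma-centered")

    rng = np.random.default_rng(cfg.seed)
    X = _subsample(X, cfg.max_points, rng)
    Y = _subsample(Y, cfg.max_points, rng)
    M, N = len(Y), len(X)

    R = np.eye(_D)
    # standard init: mean squared cross-pair distance / D
    d2 = ((X[None, :, :] - Y[:, None, :]) ** 2).sum(axis=-1)
    sigma2 = float(d2.sum() / (_D * M * N))
    sigma2 = max(sigma2, np.finfo(float).eps)

    prev_obj = np.inf
    converged_by = "max_iter"
    n_iter = 0
    P = np.full((M, N), 1.0 / M)
    nll = np.inf
    for n_iter in range(1, cfg.max_iter + 1):
        P, nll = e_step(Y, X, R, sigma2, cfg.w)
        Np = float(P.sum())
        if Np <= 0:
            break

        # M-step: rotation from SVD of A = Σ P_mn x_n y_mᵀ, det-corrected
        A = (P @ X).T @ Y                                          # (3, 3)
        U, _s, Vt = np.linalg.svd(A)
        C = np.diag([1.0, 1.0, np.sign(np.linalg.det(U @ Vt))])
        R = U @ C @ Vt

        # σ² update (s = 1, t = 0)
        xPx = float((P.sum(axis=0) * (X ** 2).sum(axis=1)).sum())
        yPy = float((P.sum(axis=1) * (Y ** 2).sum(axis=1)).sum())
        trAR = float(np.trace(A.T @ R))
        sigma2 = (xPx - 2.0 * trAR + yPy) / (Np * _D)
        sigma2 = max(sigma2, 1e-12)

        if abs(prev_obj - nll) < cfg.tol:
            converged_by = "tol"
            break
        prev_obj = nll

    corr = np.argmax(P, axis=1)
    moved = Y @ R.T
    if cfg.soft_mse:
        Pn = P / np.maximum(P.sum(axis=1, keepdims=True), np.finfo(float).tiny)
        mse = float((Pn * ((moved[:, None, :] - X[None, :, :]) ** 2)
                     .sum(axis=-1)).sum() / M)
    else:
        mse = float(((moved - X[corr]) ** 2).sum(axis=1).mean())

    return CPDResult(rotation=R, sigma2=sigma2, n_iter=n_iter,
                     converged_by=converged_by, correspondence=corr,
                     mse=mse, objective=nll)


# ---------------------------------------------------------------------------
# morphology-level dissimilarity

def pair_dissimilarity(a: TopologicalMinor, b: TopologicalMinor,
                       cfg: CPDConfig = CPDConfig()) -> float:
    """CPD registration MSE (μm²) of b's soma-centered minor cloud onto a's."""
    return cpd_rigid_rotation(b.centered_points(), a.centered_points(), cfg).mse


@dataclass
class DissimilarityMatrix:
    neuron_ids: list[str]
    values: np.ndarray              # (n, n), μm²

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame(self.values, index=self.neuron_ids,
                            columns=self.neuron_ids)


def dissimilarity_matrix(minors: list[TopologicalMinor],
                         cfg: CPDConfig = CPDConfig(),
                         symmetrize: bool = True) -> DissimilarityMatrix:
    """All-pairs CPD MSE matrix.

    Registration is directional, so both orientations of every pair are
    computed and (by default) averaged into a symmetric matrix with zero
    diagonal.  A failed pair is imputed as the matrix maximum with a
    warning.
    """
    n = len(minors)
    if n < 2:
        raise ValueError("need at least two morphologies")
    D = np.zeros((n, n))
    failures = []
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            try:
                D[i, j] = pair_dissimilarity(minors[i], minors[j], cfg)
            except AlignmentError as exc:
                failures.append((i, j, str(exc)))
                D[i, j] = np.nan
        log.debug("dissimilarity row %d/%d done", i + 1, n)
    if failures:
        warnings.warn(f"{len(failures)} pair registrations failed; "
                      "imputed as matrix maximum", stacklevel=2)
        fill = np.nanmax(D) if np.isfinite(np.nanmax(D)) else 0.0
        D = np.where(np.isnan(D), fill, D)
    if symmetrize:
        D = 0.5 * (D + D.T)
    np.fill_diagonal(D, 0.0)
    return DissimilarityMatrix([m.neuron_id for m in minors], D)


def nearest_neuron(query: TopologicalMinor, collection: list[TopologicalMinor],
                   cfg: CPDConfig = CPDConfig()) -> tuple[str, float]:
    """The collection member minimizing the registration MSE to the query
    (ties broken by collection order)."""
    if not collection:
        raise ValueError("collection must be nonempty")
    best_id, best_mse = None, np.inf
    for cand in collection:
        mse = pair_dissimilarity(query, cand, cfg)
        if mse < best_mse:
            best_id, best_mse = cand.neuron_id, mse
    return best_id, float(best_mse)
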