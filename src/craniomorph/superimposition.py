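"""Generalized Procrustes superimposition and shape-space geometry.

Shape is what remains of a landmark configuration after translation,
rotation, and scale are removed. Configurations are centred and scaled
to unit centroid size, rotated iteratively onto a running consensus
(proper rotations only — reflection to a common side is a preprocessing
step), and finally projected orthogonally into the linear tangent space
at the consensus, where ordinary Euclidean multivariate statistics
apply.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "centroid_size",
    "ordinary_procrustes_align",
    "GeneralizedProcrustesAnalysis",
    "GPAResult",
    "gpa",
    "tangent_projection",
    "procrustes_distance",
]


def centroid_size(coords: np.ndarray) -> float:
    """Square root of summed squared landmark distances to the centroid (mm)."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or len(coords) < 2:
        raise ValueError("need a (k, d) configuration with k >= 2")
    if not np.isfinite(coords).all():
        raise ValueError("configuration contains non-finite coordinates")
    centered = coords - coords.mean(axis=0)
    cs = float(np.sqrt((centered**2).sum()))
    if cs == 0.0:
        raise ValueError("degenerate configuration: all landmarks coincide")
    return cs


def _preshape(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Centre and scale to unit centroid size; return (preshape, centroid, cs)."""
    coords = np.asarray(coords, dtype=float)
    centroid = coords.mean(axis=0)
    cs = centroid_size(coords)
    return (coords - centroid) / cs, centroid, cs


def _optimal_rotation(target: np.ndarray, moving: np.ndarray) -> np.ndarray:
    """Proper rotation R minimising ||target - moving @ R||_F (Kabsch)."""
    H = moving.T @ target
    U, s, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0] * (len(s) - 1) + [d])
    return U @ D @ Vt


def ordinary_procrustes_align(a: np.ndarray, b: np.ndarray, allow_scale: bool = True,
                              ) -> tuple[np.ndarray, float, np.ndarray, float]:
    """Similarity transform of ``b`` onto ``a`` minimising summed squared distance.

    Returns ``(rotation, scale, translation, residual)`` such that
    ``scale * b @ rotation + translation`` best fits ``a``; the rotation
    is always proper (no reflection). ``residual`` is the root summed
    squared distance at the optimum.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    if (np.linalg.matrix_rank(ac, tol=1e-9) < 2
            or np.linalg.matrix_rank(bc, tol=1e-9) < 2):
        raise ValueError("rank-deficient configuration: rotation undetermined")
    R = _optimal_rotation(ac, bc)
    if allow_scale:
        num = float(np.trace(R.T @ bc.T @ ac))  # = sum of corrected singular values
        scale = num / float((bc**2).sum())
    else:
        scale = 1.0
    translation = a.mean(axis=0) - scale * b.mean(axis=0) @ R
    fitted = scale * b @ R + translation
    residual = float(np.sqrt(((a - fitted) ** 2).sum()))
    return R, scale, translation, residual


@dataclass
class GPAResult:
    """Superimposed sample: aligned unit-size configurations, original
    centroid sizes (mm), consensus shape, and tangent coordinates."""

    aligned: np.ndarray      # (n, k, 3), unit centroid size, centred
    csize: np.ndarray        # (n,) original centroid sizes in mm
    consensus: np.ndarray    # (k, 3), unit centroid size
    tangent: np.ndarray      # (n, 3k) tangent-space coordinates
    iterations: int
    converged: bool


def _canonical_rotation(consensus: np.ndarray) -> np.ndarray:
    """Rotation taking the consensus to its principal axes, with
    deterministic sign conventions, so GPA output does not depend on
    input ordering or initialisation."""
    C = consensus.T @ consensus
    w, V = np.linalg.eigh(C)
    V = V[:, ::-1].copy()  # descending variance
    canon = consensus @ V
    # Sign convention must not depend on the (arbitrary) input frame, so
    # orient the first two axes by an index-weighted first moment of the
    # canonical coordinates; the third sign follows from properness.
    weights = np.arange(1, len(consensus) + 1, dtype=float)
    for j in (0, 1):
        m = weights @ canon[:, j]
        if abs(m) < 1e-12:
            m = (canon[:, j] ** 3).sum()
        if m < 0:
            V[:, j] = -V[:, j]
            canon[:, j] = -canon[:, j]
    if np.linalg.det(V) < 0:
        V[:, 2] = -V[:, 2]
    return V


class GeneralizedProcrustesAnalysis(BaseEstimator, TransformerMixin):
    """Iterative generalized Procrustes superimposition.

    ``fit`` aligns the training sample and exposes ``consensus_``,
    ``aligned_``, ``csize_``, ``tangent_``; ``transform`` maps (new)
    configurations to tangent coordinates at the fitted consensus.

    Parameters
    ----------
    tol : float
        Convergence threshold on the Frobenius change of the consensus.
    max_iter : int
        Iteration cap; non-convergence is flagged, not raised.
    """

    def __init__(self, tol: float = 1e-10, max_iter: int = 200):
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y=None) -> "GeneralizedProcrustesAnalysis":
        X = np.asarray(X, dtype=float)
        if X.ndim != 3 or X.shape[0] < 2 or X.shape[2] != 3:
            raise ValueError(f"need (n>=2, k, 3) configurations, got {X.shape}")
        if not np.isfinite(X).all():
            raise ValueError("missing/non-finite coordinates: impute before GPA")
        n = X.shape[0]
        pre = np.empty_like(X)
        csize = np.empty(n)
        for i in range(n):
            pre[i], _, csize[i] = _preshape(X[i])
        consensus = pre[0].copy()
        converged = False
        it = 0
        for it in range(1, self.max_iter + 1):
            for i in range(n):
                pre[i] = pre[i] @ _optimal_rotation(consensus, pre[i])
            new = pre.mean(axis=0)
            new = new / np.sqrt((new**2).sum())
            delta = float(np.sqrt(((new - consensus) ** 2).sum()))
            consensus = new
            if delta < self.tol:
                converged = True
                break
        V = _canonical_rotation(consensus)
        consensus = consensus @ V
        for i in range(n):
            pre[i] = pre[i] @ V
        self.consensus_ = consensus
        self.aligned_ = pre
        self.csize_ = csize
        self.n_iter_ = it
        self.converged_ = converged
        self.tangent_ = self._project(pre)
        return self

    def _project(self, aligned: np.ndarray) -> np.ndarray:
        c = self.consensus_.ravel()
        flat = aligned.reshape(len(aligned), -1)
        return flat - (flat @ c)[:, None] * c

    def transform(self, X) -> np.ndarray:
        """Align configurations to the fitted consensus; return tangent coords."""
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[None]
        out = np.empty((len(X), self.consensus_.size))
        for i, cfg in enumerate(X):
            p, _, _ = _preshape(cfg)
            p = p @ _optimal_rotation(self.consensus_, p)
            out[i] = self._project(p[None])[0]
        return out

    def result_(self) -> GPAResult:
        return GPAResult(
            aligned=self.aligned_, csize=self.csize_, consensus=self.consensus_,
            tangent=self.tangent_, iterations=self.n_iter_, converged=self.converged_,
        )


def gpa(configs, tol: float = 1e-10, max_iter: int = 200) -> GPAResult:
    """Functional wrapper around :class:`GeneralizedProcrustesAnalysis`."""
    est = GeneralizedProcrustesAnalysis(tol=tol, max_iter=max_iter)
    est.fit(np.asarray(configs, dtype=float))
    return est.result_()


def tangent_projection(result: GPAResult) -> np.ndarray:
    """Orthogonal projection of aligned pre-shapes onto the tangent space
    at the consensus; the consensus itself maps to the zero vector."""
    c = result.consensus.ravel()
    c = c / np.linalg.norm(c)
    flat = result.aligned.reshape(len(result.aligned), -1)
    return flat - (flat @ c)[:, None] * c


def procrustes_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Full Procrustes distance between two configurations.

    Both are centred and scaled to unit centroid size; the distance is
    the residual after the optimal proper rotation and scaling,
    ``sqrt(1 - s^2)`` with ``s`` the sum of (sign-corrected) singular
    values of the cross-covariance. Zero iff the shapes coincide;
    invariant to similarity transforms of either argument.
    """
    pa, _, _ = _preshape(np.asarray(a, dtype=float))
    pb, _, _ = _preshape(np.asarray(b, dtype=float))
    if pa.shape != pb.shape:
        raise ValueError(f"landmark count mismatch {pa.shape} vs {pb.shape}")
    R = _optimal_rotation(pa, pb)
    rotated = pb @ R
    scale = float(np.trace(R.T @ pb.T @ pa))  # optimal scale of b onto a
    return float(np.sqrt(((pa - scale * rotated) ** 2).sum()))
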