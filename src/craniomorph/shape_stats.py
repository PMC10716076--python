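"""Permutation-based multivariate statistics on tangent-space shape data.

Shape samples have many more variables than specimens (3k coordinates,
tens of specimens), so classical parametric MANOVA statistics are
singular. All group and regression tests here therefore use Goodall-type
variance-ratio statistics — sums of squared tangent deviations pooled
over all shape variables — with significance from label/predictor
permutation. Ordinations are PCA of the tangent covariance and
canonical variates analysis (CVA) on a PCA-reduced subspace.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import linalg as sla
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA as _SkPCA

from .superimposition import procrustes_distance

__all__ = [
    "RegressionResult",
    "GroupTestResult",
    "CVAResult",
    "PairwiseDistanceTable",
    "shape_on_size_regression",
    "procrustes_group_anova",
    "pca",
    "TangentPCA",
    "cva",
    "CanonicalVariates",
    "pairwise_group_distance_test",
]

DEFAULT_N_PERM = 10_000


def _perm_pvalue(null: np.ndarray, observed: float) -> float:
    """(b + 1) / (m + 1) permutation p-value estimator."""
    return float((np.sum(null >= observed) + 1) / (len(null) + 1))


def _permutation_indices(rng: np.random.Generator, n: int, n_perm: int) -> np.ndarray:
    """(n_perm, n) independent uniform permutations, one per row."""
    return np.argsort(rng.random((n_perm, n)), axis=1)


# ---------------------------------------------------------------------------
# Shape ~ size regression


@dataclass(frozen=True)
class RegressionResult:
    """Multivariate shape-on-size regression summary."""

    F: float
    r2: float
    p_perm: float
    n_perm: int
    seed: Optional[int]
    df: tuple[int, int]

    @property
    def pct_explained(self) -> float:
        return 100.0 * self.r2


def shape_on_size_regression(tangent: np.ndarray, ln_csize: np.ndarray,
                             n_perm: int = DEFAULT_N_PERM,
                             seed: Optional[int] = None) -> RegressionResult:
    """Regress tangent coordinates on a scalar size predictor.

    The model SS and residual SS are pooled over all shape variables
    (Goodall-style), giving ``r2 = SS_model / SS_total`` — the fraction
    of total shape variation explained by size — and the variance ratio
    ``F = SS_model / (SS_res / (n - 2))`` with 1 and n-2 degrees of
    freedom. Significance comes from permuting the predictor across
    specimens.
    """
    Y = np.asarray(tangent, dtype=float)
    x = np.asarray(ln_csize, dtype=float)
    n = len(x)
    if Y.shape[0] != n or n < 3:
        raise ValueError("need matching tangent rows and >=3 specimens")
    xc = x - x.mean()
    sxx = float(xc @ xc)
    if sxx == 0.0:
        raise ValueError("constant size predictor: regression undefined")
    Yc = Y - Y.mean(axis=0)
    ss_total = float((Yc**2).sum())
    proj = Yc.T @ xc
    ss_model = float(proj @ proj) / sxx
    ss_res = max(ss_total - ss_model, 0.0)
    r2 = ss_model / ss_total if ss_total > 0 else 0.0
    F = np.inf if ss_res == 0 else ss_model / (ss_res / (n - 2))

    rng = np.random.default_rng(seed)
    P = _permutation_indices(rng, n, n_perm)
    Xp = xc[P].T                       # (n, n_perm) permuted centred predictors
    M = Yc.T @ Xp                      # (p, n_perm)
    ssm = (M**2).sum(axis=0) / sxx
    ssr = np.maximum(ss_total - ssm, 0.0)
    with np.errstate(divide="ignore"):
        F_null = np.where(ssr == 0, np.inf, ssm / (ssr / (n - 2)))
    return RegressionResult(
        F=float(F), r2=r2, p_perm=_perm_pvalue(F_null, F),
        n_perm=n_perm, seed=seed, df=(1, n - 2),
    )


# ---------------------------------------------------------------------------
# Procrustes (permutation) group ANOVA


@dataclass(frozen=True)
class GroupTestResult:
    F: float
    df_between: int
    df_within: int
    p_perm: float
    n_perm: int
    seed: Optional[int]


def _group_codes(labels: Sequence) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels)
    uniq, codes = np.unique(labels, return_inverse=True)
    return uniq, codes


def procrustes_group_anova(tangent: np.ndarray, labels: Sequence,
                           n_perm: int = DEFAULT_N_PERM,
                           seed: Optional[int] = None) -> GroupTestResult:
    """Goodall-type permutation ANOVA of shape against a grouping factor.

    F is the ratio of between-group to within-group summed squared
    tangent deviations, scaled by (g-1) and (n-g) degrees of freedom;
    the null distribution is obtained by permuting group labels.
    """
    Y = np.asarray(tangent, dtype=float)
    uniq, codes = _group_codes(labels)
    n, g = len(codes), len(uniq)
    if g < 2:
        raise ValueError("need at least two groups")
    counts = np.bincount(codes)
    small = uniq[counts < 2]
    if small.size:
        raise ValueError(f"groups with fewer than 2 members: {list(small)}")
    Yc = Y - Y.mean(axis=0)
    ss_total = float((Yc**2).sum())

    def ssb_for(perm_rows: np.ndarray) -> np.ndarray:
        # perm_rows: (m, n) row permutations; group c's members under the
        # permuted labelling are rows perm_rows[:, positions(c)].
        out = np.zeros(len(perm_rows))
        for c in range(g):
            pos = np.flatnonzero(codes == c)
            S = Yc[perm_rows[:, pos]].sum(axis=1)      # (m, p)
            out += (S**2).sum(axis=1) / counts[c]
        return out

    identity = np.arange(n)[None, :]
    ssb = float(ssb_for(identity)[0])
    ssw = max(ss_total - ssb, 0.0)
    F = np.inf if ssw == 0 else (ssb / (g - 1)) / (ssw / (n - g))

    rng = np.random.default_rng(seed)
    F_null = np.empty(n_perm)
    done = 0
    while done < n_perm:
        m = min(2000, n_perm - done)
        P = _permutation_indices(rng, n, m)
        ssb_p = ssb_for(P)
        ssw_p = np.maximum(ss_total - ssb_p, 0.0)
        with np.errstate(divide="ignore"):
            F_null[done:done + m] = np.where(
                ssw_p == 0, np.inf, (ssb_p / (g - 1)) / (ssw_p / (n - g))
            )
        done += m
    return GroupTestResult(
        F=float(F), df_between=g - 1, df_within=n - g,
        p_perm=_perm_pvalue(F_null, F), n_perm=n_perm, seed=seed,
    )


# ---------------------------------------------------------------------------
# PCA


class TangentPCA(BaseEstimator, TransformerMixin):
    """PCA of tangent coordinates (thin wrapper over sklearn's PCA with
    rank capped at min(n-1, p))."""

    def __init__(self, n_components: Optional[int] = None):
        self.n_components = n_components

    def fit(self, X, y=None) -> "TangentPCA":
        X = np.asarray(X, dtype=float)
        k = self.n_components or min(X.shape[0] - 1, X.shape[1])
        self._pca = _SkPCA(n_components=min(k, X.shape[0] - 1, X.shape[1]))
        self._pca.fit(X)
        self.scores_ = self._pca.transform(X)
        self.eigenvalues_ = self._pca.explained_variance_
        self.components_ = self._pca.components_
        return self

    def transform(self, X) -> np.ndarray:
        return self._pca.transform(np.asarray(X, dtype=float))


def pca(tangent: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Eigen-decomposition of the tangent covariance.

    Returns centred scores, eigenvalues (non-increasing, = per-axis
    score variances with ddof=1), and component row-vectors.
    """
    est = TangentPCA().fit(tangent)
    return est.scores_, est.eigenvalues_, est.components_


# ---------------------------------------------------------------------------
# CVA


@dataclass(frozen=True)
class CVAResult:
    cv_scores: np.ndarray            # (n, n_axes)
    pct_differentiation: np.ndarray  # (n_axes,), sums to 100
    eigenvalues: np.ndarray
    n_axes: int
    group_labels: np.ndarray


class CanonicalVariates(BaseEstimator, TransformerMixin):
    """Canonical variates analysis with PCA pre-regularisation.

    With fewer specimens than shape variables the within-group
    covariance is singular, so the data are first reduced to the
    smallest PCA subspace reaching ``retain_rule`` of total variance
    (capped at n - g axes); the canonical axes then solve the
    symmetric-definite eigenproblem B v = λ W v there. Eigenvalues give
    each axis's share of among-group differentiation.
    """

    def __init__(self, retain_rule: float = 0.95):
        self.retain_rule = retain_rule

    def fit(self, X, y) -> "CanonicalVariates":
        X = np.asarray(X, dtype=float)
        uniq, codes = _group_codes(y)
        n, g = len(codes), len(uniq)
        if g < 2:
            raise ValueError("need at least two groups")
        counts = np.bincount(codes)
        if (counts < 2).any():
            raise ValueError(
                f"groups with fewer than 2 members: {list(uniq[counts < 2])}"
            )
        full_scores, eigvals, comps = pca(X)
        cum = np.cumsum(eigvals) / eigvals.sum()
        q = int(np.searchsorted(cum, self.retain_rule) + 1)
        q = min(q, n - g, len(eigvals))
        q = max(q, 1)
        Z = full_scores[:, :q]
        m = Z.mean(axis=0)
        W = np.zeros((q, q))
        B = np.zeros((q, q))
        for c in range(g):
            Zc = Z[codes == c]
            mc = Zc.mean(axis=0)
            W += (Zc - mc).T @ (Zc - mc)
            B += counts[c] * np.outer(mc - m, mc - m)
        try:
            evals, evecs = sla.eigh(B, W)
        except sla.LinAlgError as exc:
            raise ValueError(
                f"singular within-group covariance with {q} retained PCs; "
                f"lower retain_rule below {self.retain_rule}"
            ) from exc
        order = np.argsort(evals)[::-1]
        n_axes = min(g - 1, q)
        evals = np.clip(evals[order][:n_axes], 0.0, None)
        evecs = evecs[:, order][:, :n_axes]
        for j in range(n_axes):  # deterministic axis orientation
            col = evecs[:, j]
            if col[np.argmax(np.abs(col))] < 0:
                evecs[:, j] = -col
        self.mean_ = X.mean(axis=0)
        self.pca_components_ = comps[:q]
        self.coef_ = evecs
        self.eigenvalues_ = evals
        total = evals.sum()
        self.pct_differentiation_ = (
            100.0 * evals / total if total > 0 else np.full(n_axes, np.nan)
        )
        self.n_axes_ = n_axes
        self.classes_ = uniq
        self.scores_ = Z @ evecs
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return (X - self.mean_) @ self.pca_components_.T @ self.coef_

    def result_(self, y) -> CVAResult:
        return CVAResult(
            cv_scores=self.scores_, pct_differentiation=self.pct_differentiation_,
            eigenvalues=self.eigenvalues_, n_axes=self.n_axes_,
            group_labels=np.asarray(y),
        )


def cva(tangent: np.ndarray, labels: Sequence, retain_rule: float = 0.95) -> CVAResult:
    est = CanonicalVariates(retain_rule=retain_rule).fit(tangent, labels)
    return est.result_(labels)


# ---------------------------------------------------------------------------
# Pairwise Procrustes-distance permutation tests


@dataclass(frozen=True)
class PairwiseDistanceTable:
    """Between-group mean-shape distances with per-pair permutation p.

    Pairs involving single-member groups get a distance but a NaN
    (flagged) p-value.
    """

    labels: np.ndarray
    distances: np.ndarray
    p_values: np.ndarray
    n_perm: int
    seed: Optional[int]

    def to_dataframe(self) -> pd.DataFrame:
        """Distances below the diagonal, p-values above (publication layout)."""
        g = len(self.labels)
        out = np.full((g, g), np.nan)
        for i in range(g):
            for j in range(g):
                if i > j:
                    out[i, j] = self.distances[i, j]
                elif i < j:
                    out[i, j] = self.p_values[i, j]
        return pd.DataFrame(out, index=self.labels, columns=self.labels)


def _mean_shape_distance(mean_a: np.ndarray, mean_b: np.ndarray,
                         consensus: Optional[np.ndarray]) -> float:
    if consensus is None:
        return float(np.linalg.norm(mean_a - mean_b))
    k3 = consensus.size
    ca = (consensus.ravel() + mean_a).reshape(-1, 3)
    cb = (consensus.ravel() + mean_b).reshape(-1, 3)
    return procrustes_distance(ca, cb)


def pairwise_group_distance_test(tangent: np.ndarray, labels: Sequence,
                                 consensus: Optional[np.ndarray] = None,
                                 n_perm: int = DEFAULT_N_PERM,
                                 seed: Optional[int] = None,
                                 ) -> PairwiseDistanceTable:
    """Procrustes distances between group mean shapes, with per-pair
    label-permutation significance.

    Group means are taken in tangent coordinates; when the GPA
    ``consensus`` is supplied the means are mapped back to landmark
    configurations and compared by full Procrustes distance, otherwise
    by Euclidean tangent distance (the two agree to first order near
    the consensus).
    """
    Y = np.asarray(tangent, dtype=float)
    uniq, codes = _group_codes(labels)
    g = len(uniq)
    rng = np.random.default_rng(seed)
    D = np.zeros((g, g))
    P = np.full((g, g), np.nan)
    for a in range(g):
        for b in range(a + 1, g):
            ia = np.flatnonzero(codes == a)
            ib = np.flatnonzero(codes == b)
            ma, mb = Y[ia].mean(axis=0), Y[ib].mean(axis=0)
            d_obs = _mean_shape_distance(ma, mb, consensus)
            D[a, b] = D[b, a] = d_obs
            if len(ia) < 2 or len(ib) < 2:
                continue  # distance reported, p not testable
            pool = Y[np.concatenate([ia, ib])]
            na = len(ia)
            null = np.empty(n_perm)
            for r in range(n_perm):
                perm = rng.permutation(len(pool))
                null[r] = _mean_shape_distance(
                    pool[perm[:na]].mean(axis=0),
                    pool[perm[na:]].mean(axis=0),
                    consensus,
                )
            P[a, b] = P[b, a] = _perm_pvalue(null, d_obs)
    return PairwiseDistanceTable(
        labels=uniq, distances=D, p_values=P, n_perm=n_perm, seed=seed
    )
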