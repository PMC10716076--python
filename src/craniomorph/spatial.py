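"""Spatial autocorrelation of site-level morphometric summaries.

Isolation by distance — the population-history signature in which
nearby populations resemble each other more than distant ones — is
assessed with Moran's I correlograms: between-site great-circle
distances are binned into equal-width classes (100 km by default) and
Moran's I is computed per class with binary class-membership weights,

    I = (n / W) * sum_ij w_ij (x_i - xbar)(x_j - xbar) / sum_i (x_i - xbar)^2

with deviations from the plain mean and the maximum-likelihood variance
in the denominator (division by n, not n-1). Under spatial randomness
E[I] = -1/(n-1); significance is a two-sided permutation test around
that expectation, shuffling values across sites with the same
permutations shared by every distance class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io import SiteInfo

__all__ = [
    "EARTH_RADIUS_KM",
    "great_circle_distance_matrix",
    "haversine_km",
    "DistanceClass",
    "build_distance_classes",
    "morans_i",
    "Correlogram",
    "correlogram",
    "site_summaries",
]

EARTH_RADIUS_KM = 6371.0088  # IUGG mean Earth radius


def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance between decimal-degree coordinates (km)."""
    lat1, lon1, lat2, lon2 = map(np.radians, map(np.asarray, (lat1, lon1, lat2, lon2)))
    a = (np.sin((lat2 - lat1) / 2) ** 2
         + np.cos(lat1) * np.cos(lat2) * np.sin((lon2 - lon1) / 2) ** 2)
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def great_circle_distance_matrix(sites: Sequence[SiteInfo]) -> pd.DataFrame:
    """Symmetric between-site haversine distance matrix in km."""
    lats = np.array([s.latitude for s in sites], dtype=float)
    lons = np.array([s.longitude for s in sites], dtype=float)
    if not (np.isfinite(lats).all() and np.isfinite(lons).all()):
        bad = [s.site for s in sites
               if not (np.isfinite(s.latitude) and np.isfinite(s.longitude))]
        raise ValueError(f"sites without coordinates: {bad}")
    D = haversine_km(lats[:, None], lons[:, None], lats[None, :], lons[None, :])
    np.fill_diagonal(D, 0.0)
    names = [s.site for s in sites]
    return pd.DataFrame(D, index=names, columns=names)


@dataclass(frozen=True)
class DistanceClass:
    """One half-open distance bin [lower_km, upper_km) and its site pairs."""

    class_id: int                      # 1-based
    lower_km: float
    upper_km: float
    member_pairs: tuple[tuple[int, int], ...]  # 0-based site index pairs (i < j)
    mean_distance_km: float

    @property
    def n_pairs(self) -> int:
        return len(self.member_pairs)

    def weight_matrix(self, n_sites: int) -> np.ndarray:
        """Symmetric binary membership matrix for this class."""
        W = np.zeros((n_sites, n_sites))
        for i, j in self.member_pairs:
            W[i, j] = W[j, i] = 1.0
        return W


def build_distance_classes(distmat, width_km: float = 100.0) -> list[DistanceClass]:
    """Bin every off-diagonal site pair into equal-width distance classes.

    Classes run [0, w), [w, 2w), ... up to the class containing the
    maximum between-site distance; empty classes are retained with
    ``n_pairs == 0`` so correlogram tables keep a fixed class axis.
    """
    D = np.asarray(distmat, dtype=float)
    if width_km <= 0:
        raise ValueError("class width must be positive")
    n = D.shape[0]
    iu, ju = np.triu_indices(n, 1)
    d = D[iu, ju]
    n_classes = int(np.floor(d.max() / width_km)) + 1
    classes = []
    for c in range(n_classes):
        lo, hi = c * width_km, (c + 1) * width_km
        in_class = (d >= lo) & (d < hi)
        pairs = tuple(zip(iu[in_class].tolist(), ju[in_class].tolist()))
        mean = float(d[in_class].mean()) if in_class.any() else np.nan
        classes.append(DistanceClass(c + 1, lo, hi, pairs, mean))
    return classes


def morans_i(values: Sequence[float], weights: np.ndarray) -> float:
    """Moran's I with binary weights and the ML (divide-by-n) variance.

    Raises on constant values; returns NaN when the weight matrix has
    no nonzero entry (no pairs join any sites at this distance).
    """
    x = np.asarray(values, dtype=float)
    W = np.asarray(weights, dtype=float)
    n = len(x)
    if W.shape != (n, n) or not np.allclose(W, W.T) or np.diag(W).any():
        raise ValueError("weights must be symmetric with zero diagonal")
    w_sum = W.sum()
    if w_sum == 0:
        return float("nan")
    dev = x - x.mean()
    denom = float((dev**2).sum())
    if denom == 0.0:
        raise ValueError("constant values: Moran's I undefined (zero variance)")
    num = float(dev @ W @ dev)
    return (n / w_sum) * num / denom


@dataclass(frozen=True)
class Correlogram:
    """Per-class Moran's I, permutation p, and pair counts for one variable."""

    variable: str
    class_id: np.ndarray
    mean_distance_km: np.ndarray
    morans_I: np.ndarray
    p_perm: np.ndarray
    n_pairs: np.ndarray
    n_perm: int
    seed: Optional[int]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "distance_class": self.class_id,
                "mean_distance_km": self.mean_distance_km,
                "morans_I": self.morans_I,
                "p": self.p_perm,
                "n_pairs": self.n_pairs,
            }
        )


def correlogram(site_values: Sequence[float], distmat, width_km: float = 100.0,
                n_perm: int = 999, seed: Optional[int] = None,
                variable: str = "value") -> Correlogram:
    """Moran's I across distance classes with shared-permutation p-values.

    ``site_values`` aligns with the rows of ``distmat``; NaN entries
    mark sites without data, which are excluded pairwise. Classes whose
    pairs all involve excluded sites (or that are empty) are flagged
    undefined (NaN I and p). p-values are two-sided around the null
    expectation -1/(n-1); one set of permutations of the observed
    values across data-bearing sites is shared by all classes.
    """
    x = np.asarray(site_values, dtype=float)
    D = np.asarray(distmat, dtype=float)
    have = np.isfinite(x)
    idx = np.flatnonzero(have)
    xs = x[idx]
    Ds = D[np.ix_(idx, idx)]
    n = len(xs)
    classes = build_distance_classes(D, width_km)
    n_classes = len(classes)
    I_obs = np.full(n_classes, np.nan)
    p_out = np.full(n_classes, np.nan)
    n_pairs = np.zeros(n_classes, dtype=int)
    mean_d = np.array([c.mean_distance_km for c in classes])

    if n >= 2 and np.ptp(xs) > 0:
        sub_classes = build_distance_classes(Ds, width_km)
        rng = np.random.default_rng(seed)
        perms = np.argsort(rng.random((n_perm, n)), axis=1)
        Xp = xs[perms]                       # shared across classes
        e_null = -1.0 / (n - 1)
        dev = Xp - Xp.mean(axis=1, keepdims=True)
        denom = (dev**2).sum(axis=1)
        dev0 = xs - xs.mean()
        denom0 = float((dev0**2).sum())
        for c in sub_classes:
            if c.class_id > n_classes or c.n_pairs == 0:
                continue
            k = c.class_id - 1
            W = c.weight_matrix(n)
            w_sum = W.sum()
            n_pairs[k] = c.n_pairs
            I = (n / w_sum) * float(dev0 @ W @ dev0) / denom0
            I_obs[k] = I
            null = (n / w_sum) * np.einsum("ri,ij,rj->r", dev, W, dev) / denom
            p_out[k] = (np.sum(np.abs(null - e_null) >= abs(I - e_null)) + 1) / (n_perm + 1)
    # class-level pair counts over ALL sites (for reporting)
    for c in classes:
        if n_pairs[c.class_id - 1] == 0:
            # count pairs among data-bearing sites; stays 0 if none
            kept = sum(1 for i, j in c.member_pairs if have[i] and have[j])
            n_pairs[c.class_id - 1] = kept
    return Correlogram(
        variable=variable,
        class_id=np.arange(1, n_classes + 1),
        mean_distance_km=mean_d,
        morans_I=I_obs,
        p_perm=p_out,
        n_pairs=n_pairs,
        n_perm=n_perm,
        seed=seed,
    )


def site_summaries(dataset, gpa_result, n_pcs: int = 2) -> pd.DataFrame:
    """Per-site mean centroid size and mean PC scores.

    PCA is computed on the pooled tangent coordinates; sites with zero
    specimens in the dataset are simply absent from the output (a
    warning is the caller's concern when joining to a site list).
    """
    from .shape_stats import pca as _pca

    scores, _, _ = _pca(gpa_result.tangent)
    rows = []
    site_names = [r.site for r in dataset.specimens]
    df = pd.DataFrame(
        {
            "site": site_names,
            "csize": gpa_result.csize,
            **{f"PC{k + 1}": scores[:, k] for k in range(min(n_pcs, scores.shape[1]))},
        }
    )
    out = df.groupby("site", sort=False).mean().reset_index()
    out["n_specimens"] = df.groupby("site", sort=False).size().to_numpy()
    return out
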