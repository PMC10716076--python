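"""Reflection and mirror imputation of missing bilateral landmarks.

Fragmentary crania often preserve a landmark on one side only. Because
the cranium is approximately bilaterally symmetric, a missing landmark
whose mirror partner is present can be estimated by reflecting the
partner through the specimen's own midline plane. The midline is fitted
per specimen, in least squares, from all its present landmarks: midline
landmarks should lie on the plane, and each complete bilateral pair
should be mirror-symmetric about it (pair midpoint on the plane, pair
difference vector parallel to the plane normal).

Specimens missing more than ``max_missing`` landmarks (default 3, i.e.
imputation only where fewer than four are missing) are left untouched
and flagged excluded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .io import AnnotatedDataset, SpecimenRecord
from .landmark_sets import LandmarkSetSpec

__all__ = [
    "MidlinePlane",
    "MidlineEstimationError",
    "estimate_midline",
    "reflect_configuration",
    "reflect_points",
    "impute_missing_bilateral",
    "impute_dataset",
    "subset_complete",
    "BilateralImputer",
]


class MidlineEstimationError(ValueError):
    """Too little symmetry information to fit a midline plane."""


@dataclass(frozen=True)
class MidlinePlane:
    """Plane through ``point`` with unit ``normal``."""

    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "point", np.asarray(self.point, dtype=float))
        object.__setattr__(self, "normal", np.asarray(self.normal, dtype=float))
        n = np.linalg.norm(self.normal)
        if abs(n - 1.0) > 1e-12:
            if n == 0:
                raise ValueError("plane normal must be nonzero")
            object.__setattr__(self, "normal", self.normal / n)


def reflect_points(points: np.ndarray, plane: MidlinePlane) -> np.ndarray:
    """Mirror 3D points through a plane (isometry)."""
    points = np.asarray(points, dtype=float)
    d = (points - plane.point) @ plane.normal
    return points - 2.0 * d[..., None] * plane.normal


def _fix_sign(v: np.ndarray) -> np.ndarray:
    for x in v:
        if abs(x) > 1e-12:
            return v if x > 0 else -v
    return v


def estimate_midline(record: SpecimenRecord, spec: LandmarkSetSpec) -> MidlinePlane:
    """Least-squares symmetry plane from present landmarks.

    Minimises the sum of squared plane distances of present midline
    landmarks and complete-pair midpoints, plus the squared off-normal
    components of pair difference vectors. For a fixed normal the
    optimal offset puts the plane through the mean of the on-plane
    constraint points, reducing the problem to the smallest eigenvector
    of the symmetric matrix A - D (A: scatter of on-plane points, D:
    sum of pair-difference outer products). The normal's sign is fixed
    so its first non-negligible component is positive.
    """
    mid = [record.coords[i] for i in spec.midline_indices if record.present[i]]
    diffs, midpoints = [], []
    for li, ri in spec.bilateral_pairs:
        if record.present[li] and record.present[ri]:
            diffs.append(record.coords[li] - record.coords[ri])
            midpoints.append(0.5 * (record.coords[li] + record.coords[ri]))
    onplane = np.array(mid + midpoints, dtype=float).reshape(-1, 3)
    if len(diffs) == 0:
        if len(mid) < 3:
            raise MidlineEstimationError(
                f"{record.specimen_id}: need >=1 complete bilateral pair or >=3 "
                f"midline landmarks ({len(mid)} midline, 0 pairs present)"
            )
        centered = onplane - onplane.mean(axis=0)
        if np.linalg.matrix_rank(centered, tol=1e-9) < 2:
            raise MidlineEstimationError(
                f"{record.specimen_id}: midline landmarks are collinear"
            )
    q = onplane.mean(axis=0)
    centered = onplane - q
    A = centered.T @ centered
    D = np.zeros((3, 3))
    for d in diffs:
        D += np.outer(d, d)
    w, V = np.linalg.eigh(A - D)
    normal = _fix_sign(V[:, 0])
    return MidlinePlane(point=q, normal=normal)


def reflect_configuration(record: SpecimenRecord, spec: LandmarkSetSpec,
                          plane: MidlinePlane) -> SpecimenRecord:
    """Mirror a configuration through a plane, relabelling left/right pairs.

    After mirroring, what was the anatomical left lies on the right, so
    the rows of each bilateral pair are swapped to keep labels attached
    to the correct anatomical structures. Centroid size is preserved
    (reflection is an isometry).
    """
    out = record.copy()
    mirrored = reflect_points(record.coords, plane)
    coords = mirrored.copy()
    present = record.present.copy()
    imputed = record.imputed.copy()
    for li, ri in spec.bilateral_pairs:
        coords[[li, ri]] = mirrored[[ri, li]]
        present[[li, ri]] = record.present[[ri, li]]
        imputed[[li, ri]] = record.imputed[[ri, li]]
    coords[~present] = np.nan
    out.coords, out.present, out.imputed = coords, present, imputed
    return out


@dataclass
class SpecimenCompleteness:
    specimen_id: str
    n_missing_before: int
    n_imputed: int
    n_missing_after: int
    excluded: bool
    note: str = ""


def impute_missing_bilateral(record: SpecimenRecord, spec: LandmarkSetSpec,
                             max_missing: int = 3,
                             ) -> tuple[SpecimenRecord, SpecimenCompleteness]:
    """Fill missing bilateral landmarks by reflecting their partners.

    Records missing more than ``max_missing`` landmarks are returned
    unchanged and flagged excluded. Missing midline landmarks and pairs
    with both sides absent cannot be mirror-imputed and are left
    missing; such cases are reported, never raised.
    """
    n_before = record.n_missing
    if n_before > max_missing:
        return record.copy(), SpecimenCompleteness(
            record.specimen_id, n_before, 0, n_before, True,
            f"more than {max_missing} landmarks missing",
        )
    if n_before == 0:
        return record.copy(), SpecimenCompleteness(record.specimen_id, 0, 0, 0, False)
    try:
        plane = estimate_midline(record, spec)
    except MidlineEstimationError as exc:
        return record.copy(), SpecimenCompleteness(
            record.specimen_id, n_before, 0, n_before, False, f"midline not estimable: {exc}"
        )
    out = record.copy()
    n_imputed = 0
    for li, ri in spec.bilateral_pairs:
        for miss, part in ((li, ri), (ri, li)):
            if not record.present[miss] and record.present[part]:
                out.coords[miss] = reflect_points(record.coords[part], plane)
                out.present[miss] = True
                out.imputed[miss] = True
                n_imputed += 1
    return out, SpecimenCompleteness(
        record.specimen_id, n_before, n_imputed, n_before - n_imputed, False
    )


def impute_dataset(dataset: AnnotatedDataset, max_missing: int = 3,
                   ) -> tuple[AnnotatedDataset, pd.DataFrame]:
    """Apply mirror imputation to every specimen; return dataset + report."""
    records, rows = [], []
    for r in dataset.specimens:
        out, rep = impute_missing_bilateral(r, dataset.spec, max_missing)
        records.append(out)
        rows.append(rep.__dict__)
    report = pd.DataFrame(rows)
    return AnnotatedDataset(dataset.spec, records, dataset.sites), report


def subset_complete(dataset: AnnotatedDataset, target_spec: LandmarkSetSpec,
                    ) -> AnnotatedDataset:
    """Project to a target landmark set, keeping only complete specimens."""
    pos = list(target_spec.positions_in(dataset.spec))
    records = []
    for r in dataset.specimens:
        if r.present[pos].all():
            records.append(
                SpecimenRecord(
                    r.specimen_id, r.coords[pos], r.present[pos],
                    r.site, r.sex, r.imputed[pos],
                )
            )
    if not records:
        warnings.warn(
            f"no specimen is complete for landmark set {target_spec.set_id!r}",
            stacklevel=2,
        )
    return AnnotatedDataset(target_spec, records, dataset.sites)


class BilateralImputer(BaseEstimator, TransformerMixin):
    """Mirror-imputation step usable in sklearn pipelines.

    Parameters
    ----------
    max_missing : int, default 3
        Specimens with more missing landmarks than this are passed
        through untouched and flagged excluded in ``report_``.
    """

    def __init__(self, max_missing: int = 3):
        self.max_missing = max_missing

    def fit(self, X: AnnotatedDataset, y=None) -> "BilateralImputer":
        # Stateless: the midline is refitted per specimen at transform time.
        return self

    def transform(self, X: AnnotatedDataset) -> AnnotatedDataset:
        out, report = impute_dataset(X, self.max_missing)
        self.report_ = report
        return out
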