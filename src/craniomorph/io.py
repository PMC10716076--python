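"""Reading and writing landmark coordinate files and specimen metadata.

Supported formats:

* **TPS** — the classic landmark interchange format. Blocks start with
  ``LM=<n>`` or ``LM3=<n>``; each of the following *n* lines holds one
  landmark's coordinates; ``ID=`` names the specimen and an optional
  ``SCALE=`` line multiplies all coordinates. TPS has no standard
  missing-data encoding, so a sentinel coordinate value (default
  ``-9999.0``) marks absent landmarks.
* **CSV long** — columns ``specimen_id, landmark_index, x, y, z``;
  empty coordinate cells mark absent landmarks.
* **CSV wide** — one row per specimen, columns ``<name>_x/_y/_z``.

Coordinates are millimetres throughout; identifiers are case-sensitive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .landmark_sets import LandmarkSetSpec

__all__ = [
    "DIET_GROUPS",
    "MISSING_SENTINEL",
    "SpecimenRecord",
    "SiteInfo",
    "AnnotatedDataset",
    "FormatError",
    "read_landmark_table",
    "write_landmark_table",
    "read_tps",
    "write_tps",
    "read_csv_long",
    "write_csv_long",
    "attach_metadata",
    "load_site_table",
    "load_site_distance_matrix",
]

DIET_GROUPS = ("HOK", "NEH", "CCH", "ICH", "SWJ")
MISSING_SENTINEL = -9999.0

PathLike = Union[str, Path]


class FormatError(ValueError):
    """Malformed landmark file or metadata table."""


@dataclass
class SpecimenRecord:
    """One specimen's 3D landmark configuration plus metadata.

    ``coords`` is an (n_landmarks, 3) float array in mm; ``present`` a
    boolean mask. Coordinates of absent landmarks are NaN in memory.
    ``imputed`` flags landmarks filled in by mirror imputation.
    """

    specimen_id: str
    coords: np.ndarray
    present: np.ndarray
    site: str = ""
    sex: str = "U"
    imputed: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError(
                f"{self.specimen_id}: coords must be (n, 3), got {self.coords.shape}"
            )
        if self.present is None:
            self.present = np.ones(len(self.coords), dtype=bool)
        self.present = np.asarray(self.present, dtype=bool)
        if self.present.shape != (len(self.coords),):
            raise ValueError(f"{self.specimen_id}: present mask shape mismatch")
        if self.imputed is None:
            self.imputed = np.zeros(len(self.coords), dtype=bool)
        self.imputed = np.asarray(self.imputed, dtype=bool)
        if not self.present.any():
            raise ValueError(f"{self.specimen_id}: no landmarks present")
        if not np.isfinite(self.coords[self.present]).all():
            raise ValueError(f"{self.specimen_id}: non-finite coordinates where present")
        if self.sex not in ("F", "M", "U"):
            raise ValueError(f"{self.specimen_id}: sex must be F/M/U, got {self.sex!r}")
        self.coords = self.coords.copy()
        self.coords[~self.present] = np.nan

    @property
    def n_landmarks(self) -> int:
        return len(self.coords)

    @property
    def n_missing(self) -> int:
        return int((~self.present).sum())

    def copy(self) -> "SpecimenRecord":
        return SpecimenRecord(
            self.specimen_id,
            self.coords.copy(),
            self.present.copy(),
            self.site,
            self.sex,
            self.imputed.copy(),
        )


@dataclass(frozen=True)
class SiteInfo:
    """Archaeological site with diet-group allocation and coordinates.

    Latitude/longitude may be NaN when unknown (the published site table
    prints between-site distances, not coordinates).
    """

    site: str
    diet_group: str
    latitude: float = math.nan
    longitude: float = math.nan

    def __post_init__(self) -> None:
        if self.diet_group not in DIET_GROUPS:
            raise ValueError(
                f"site {self.site!r}: diet group {self.diet_group!r} not in {DIET_GROUPS}"
            )
        if math.isfinite(self.latitude) and abs(self.latitude) > 90:
            raise ValueError(f"site {self.site!r}: |latitude| > 90")
        if math.isfinite(self.longitude) and abs(self.longitude) > 180:
            raise ValueError(f"site {self.site!r}: |longitude| > 180")


@dataclass
class AnnotatedDataset:
    """Landmark spec + specimens + site metadata, cross-validated."""

    spec: LandmarkSetSpec
    specimens: list[SpecimenRecord]
    sites: list[SiteInfo]

    def __post_init__(self) -> None:
        site_names = [s.site for s in self.sites]
        if len(set(site_names)) != len(site_names):
            raise ValueError("duplicate sites in site table")
        lookup = set(site_names)
        for r in self.specimens:
            if r.n_landmarks != self.spec.n_landmarks:
                raise ValueError(
                    f"{r.specimen_id}: {r.n_landmarks} landmarks, "
                    f"spec {self.spec.set_id} has {self.spec.n_landmarks}"
                )
            if r.site and r.site not in lookup:
                raise KeyError(f"{r.specimen_id}: unknown site {r.site!r}")

    @property
    def site_by_name(self) -> dict[str, SiteInfo]:
        return {s.site: s for s in self.sites}

    def diet_group_of(self, specimen: SpecimenRecord) -> str:
        return self.site_by_name[specimen.site].diet_group

    def diet_groups(self) -> np.ndarray:
        m = self.site_by_name
        return np.array([m[r.site].diet_group for r in self.specimens])

    def coords_array(self) -> np.ndarray:
        """Stack all configurations into (n_specimens, n_landmarks, 3)."""
        return np.stack([r.coords for r in self.specimens])


# ---------------------------------------------------------------------------
# TPS

def read_tps(path: PathLike, missing_sentinel: float = MISSING_SENTINEL) -> list[SpecimenRecord]:
    """Parse a 3D TPS file into specimen records."""
    records: list[SpecimenRecord] = []
    lines = Path(path).read_text().splitlines()
    i, n_expected = 0, None
    while i < len(lines):
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        upper = line.upper()
        if not (upper.startswith("LM=") or upper.startswith("LM3=")):
            raise FormatError(f"{path}:{i + 1}: expected LM=/LM3= header, got {line!r}")
        try:
            n_lm = int(line.split("=", 1)[1])
        except ValueError:
            raise FormatError(f"{path}:{i + 1}: bad landmark count in {line!r}")
        i += 1
        pts = []
        while len(pts) < n_lm:
            if i >= len(lines):
                raise FormatError(f"{path}: truncated block (expected {n_lm} landmarks)")
            row = lines[i].split()
            if len(row) != 3:
                raise FormatError(
                    f"{path}:{i + 1}: expected 3 coordinates per landmark, got {len(row)}"
                )
            try:
                pts.append([float(v) for v in row])
            except ValueError:
                raise FormatError(f"{path}:{i + 1}: non-numeric coordinate in {lines[i]!r}")
            i += 1
        spec_id, scale = f"specimen_{len(records) + 1}", 1.0
        while i < len(lines):
            tail = lines[i].strip()
            u = tail.upper()
            if u.startswith("ID="):
                spec_id = tail.split("=", 1)[1].strip()
                i += 1
            elif u.startswith("SCALE="):
                try:
                    scale = float(tail.split("=", 1)[1])
                except ValueError:
                    raise FormatError(f"{path}:{i + 1}: non-numeric SCALE")
                i += 1
            elif u.startswith("IMAGE=") or not tail:
                i += 1
            else:
                break
        coords = np.asarray(pts, dtype=float)
        present = ~np.all(coords == missing_sentinel, axis=1)
        coords = coords * scale
        coords[~present] = np.nan
        if n_expected is None:
            n_expected = n_lm
        elif n_lm != n_expected:
            raise FormatError(
                f"{path}: specimen {spec_id!r} has {n_lm} landmarks, expected {n_expected}"
            )
        records.append(SpecimenRecord(spec_id, coords, present))
    return records


def write_tps(path: PathLike, records: Sequence[SpecimenRecord],
              missing_sentinel: float = MISSING_SENTINEL) -> None:
    out = []
    for r in records:
        out.append(f"LM3={r.n_landmarks}")
        for p, ok in zip(r.coords, r.present):
            if ok:
                out.append(f"{p[0]:.9f} {p[1]:.9f} {p[2]:.9f}")
            else:
                out.append(f"{missing_sentinel} {missing_sentinel} {missing_sentinel}")
        out.append(f"ID={r.specimen_id}")
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# CSV (long format)

def read_csv_long(path: PathLike) -> list[SpecimenRecord]:
    """Read ``specimen_id, landmark_index, x, y, z`` CSV; empty cells = absent."""
    df = pd.read_csv(path, dtype={"specimen_id": str})
    required = {"specimen_id", "landmark_index", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: need columns {sorted(required)}")
    records = []
    n_expected = None
    for spec_id, grp in df.groupby("specimen_id", sort=False):
        grp = grp.sort_values("landmark_index")
        idx = grp["landmark_index"].to_numpy()
        if not np.array_equal(idx, np.arange(1, len(idx) + 1)):
            raise FormatError(f"{path}: specimen {spec_id!r} landmark_index not 1..n")
        if n_expected is None:
            n_expected = len(idx)
        elif len(idx) != n_expected:
            raise FormatError(
                f"{path}: specimen {spec_id!r} has {len(idx)} landmarks, expected {n_expected}"
            )
        coords = grp[["x", "y", "z"]].to_numpy(dtype=float)
        present = np.isfinite(coords).all(axis=1)
        records.append(SpecimenRecord(str(spec_id), coords, present))
    return records


def write_csv_long(path: PathLike, records: Sequence[SpecimenRecord]) -> None:
    rows = []
    for r in records:
        for j, (p, ok) in enumerate(zip(r.coords, r.present), start=1):
            rows.append(
                {
                    "specimen_id": r.specimen_id,
                    "landmark_index": j,
                    "x": p[0] if ok else np.nan,
                    "y": p[1] if ok else np.nan,
                    "z": p[2] if ok else np.nan,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.9f")


def read_landmark_table(path: PathLike, format: str = None) -> list[SpecimenRecord]:
    """Dispatch on format ('tps' or 'csv'); inferred from suffix if omitted."""
    fmt = format or ("tps" if str(path).lower().endswith(".tps") else "csv")
    if fmt == "tps":
        return read_tps(path)
    if fmt == "csv":
        return read_csv_long(path)
    raise ValueError(f"unknown landmark format {fmt!r}")


def write_landmark_table(path: PathLike, records: Sequence[SpecimenRecord],
                         format: str = None) -> None:
    fmt = format or ("tps" if str(path).lower().endswith(".tps") else "csv")
    if fmt == "tps":
        write_tps(path, records)
    elif fmt == "csv":
        write_csv_long(path, records)
    else:
        raise ValueError(f"unknown landmark format {fmt!r}")


# ---------------------------------------------------------------------------
# Metadata

def _sites_from_table(table: Union[pd.DataFrame, PathLike]) -> list[SiteInfo]:
    df = table if isinstance(table, pd.DataFrame) else pd.read_csv(table)
    if not {"site", "diet_group"}.issubset(df.columns):
        raise FormatError("site table needs columns: site, diet_group[, latitude, longitude]")
    sites = []
    for _, row in df.iterrows():
        group = str(row["diet_group"]).strip().upper()
        sites.append(
            SiteInfo(
                site=str(row["site"]),
                diet_group=group,
                latitude=float(row.get("latitude", math.nan) or math.nan)
                if "latitude" in df.columns else math.nan,
                longitude=float(row.get("longitude", math.nan) or math.nan)
                if "longitude" in df.columns else math.nan,
            )
        )
    return sites


def attach_metadata(records: Sequence[SpecimenRecord],
                    sites_table: Union[pd.DataFrame, PathLike],
                    spec: LandmarkSetSpec,
                    specimen_table: Union[pd.DataFrame, PathLike, None] = None,
                    ) -> AnnotatedDataset:
    """Assemble a validated dataset from records + site (and specimen) metadata.

    ``specimen_table`` (columns ``specimen_id, site[, sex]``) fills in
    per-specimen site and sex when the records do not carry them already.
    Unknown sites raise ``KeyError``; diet codes outside the five groups
    raise ``ValueError``.
    """
    sites = _sites_from_table(sites_table)
    records = [r.copy() for r in records]
    if specimen_table is not None:
        meta = (specimen_table if isinstance(specimen_table, pd.DataFrame)
                else pd.read_csv(specimen_table, dtype=str))
        meta = meta.set_index("specimen_id")
        if meta.index.has_duplicates:
            raise FormatError("duplicate specimen_id in specimen table")
        for r in records:
            if r.specimen_id not in meta.index:
                raise KeyError(f"specimen {r.specimen_id!r} not in specimen table")
            row = meta.loc[r.specimen_id]
            r.site = str(row["site"])
            if "sex" in meta.columns and isinstance(row.get("sex"), str):
                r.sex = row["sex"].strip().upper() or "U"
    return AnnotatedDataset(spec=spec, specimens=records, sites=sites)


# ---------------------------------------------------------------------------
# Bundled fixtures (published site table and between-site distances)

def load_site_table() -> pd.DataFrame:
    """The 16-site table: site, diet_group, published sample size, map number."""
    with resources.files("craniomorph.data").joinpath("sites.csv").open() as fh:
        return pd.read_csv(fh)


def load_site_distance_matrix() -> pd.DataFrame:
    """The published 16x16 between-site great-circle distance matrix (km)."""
    with resources.files("craniomorph.data").joinpath("site_distances_km.csv").open() as fh:
        df = pd.read_csv(fh, index_col=0)
    df.columns.name = None
    return df
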