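"""Landmark-based relative bite-force estimation and group comparison.

The bite-force score treats the cranium as a lever: the temporalis and
masseter muscles, whose sizes are proxied by the centroid sizes of the
landmarks and semilandmarks delimiting them (TCS, MCS, in mm), act at
lever arms *t* and *m* — the distances from each muscle's landmark
centroid to the temporomandibular joint (TMJ) — against the moment arm
*Mo* from the TMJ to the bite point at the second molar (M2):

    BF = (TCS * t + MCS * m) / Mo

BF is a dimensionless-by-convention relative score (mm^2/mm scale), not
Newtons; it scales linearly with specimen size and is invariant to
rigid motion. Semilandmarks contribute to muscle centroid sizes only —
they never enter shape analyses and are never slid.

Group comparison follows the standard univariate pipeline: drop groups
with fewer than two members, Shapiro-Wilk normality per group, Levene's
test (Brown-Forsythe, median-centred) for homogeneity of variance, then
Welch's ANOVA when variances are heterogeneous or the classical one-way
ANOVA otherwise, with Tukey HSD post-hoc comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .io import AnnotatedDataset, SpecimenRecord
from .superimposition import centroid_size

__all__ = [
    "BiteForceRoleMap",
    "BiteForceResult",
    "estimate_bite_force",
    "bite_force_table",
    "compare_groups_univariate",
    "GroupComparisonReport",
]


@dataclass(frozen=True)
class BiteForceRoleMap:
    """1-based ordinals assigning bite-force landmarks to their roles.

    Defaults follow the published design: landmarks 2-4 and 9-12 plus
    semilandmarks 16-26 delimit the temporalis; landmark 1, landmarks
    5-8, and semilandmarks 13-15 delimit the masseter; the TMJ and the
    M2 bite point are separate reference points (27 and 28 in the
    bundled set).
    """

    temporalis_indices: tuple[int, ...] = (2, 3, 4, 9, 10, 11, 12,
                                           16, 17, 18, 19, 20, 21, 22, 23, 24, 25, 26)
    masseter_indices: tuple[int, ...] = (1, 5, 6, 7, 8, 13, 14, 15)
    tmj_index: int = 27
    bitepoint_index: int = 28

    def __post_init__(self) -> None:
        t, m = set(self.temporalis_indices), set(self.masseter_indices)
        if t & m:
            raise ValueError(f"temporalis/masseter overlap: {sorted(t & m)}")
        for ref in (self.tmj_index, self.bitepoint_index):
            if ref in t or ref in m:
                raise ValueError(f"reference landmark {ref} inside a muscle set")
        if self.tmj_index == self.bitepoint_index:
            raise ValueError("TMJ and bite point must differ")


@dataclass(frozen=True)
class BiteForceResult:
    """Per-specimen lever-model quantities (mm) and the BF score."""

    specimen_id: str
    TCS: float
    MCS: float
    t: float
    m: float
    Mo: float

    @property
    def BF(self) -> float:
        return (self.TCS * self.t + self.MCS * self.m) / self.Mo


def _subset(record: SpecimenRecord, ordinals: Sequence[int]) -> np.ndarray:
    idx = [i - 1 for i in ordinals]
    missing = [i + 1 for i in idx if not record.present[i]]
    if missing:
        raise ValueError(
            f"{record.specimen_id}: bite-force landmarks missing at ordinals {missing}"
        )
    return record.coords[idx]


def estimate_bite_force(record: SpecimenRecord,
                        roles: BiteForceRoleMap = BiteForceRoleMap(),
                        ) -> BiteForceResult:
    """Compute the lever-model bite-force score for one specimen.

    All quantities use raw millimetre coordinates (size must be kept
    for BF to carry size information). Lever arms run from each muscle
    subset's landmark centroid to the TMJ; the moment arm from the TMJ
    to the M2 bite point.
    """
    temp = _subset(record, roles.temporalis_indices)
    mass = _subset(record, roles.masseter_indices)
    tmj = _subset(record, [roles.tmj_index])[0]
    bite = _subset(record, [roles.bitepoint_index])[0]
    TCS = centroid_size(temp)
    MCS = centroid_size(mass)
    t = float(np.linalg.norm(temp.mean(axis=0) - tmj))
    m = float(np.linalg.norm(mass.mean(axis=0) - tmj))
    Mo = float(np.linalg.norm(tmj - bite))
    if Mo == 0.0:
        raise ValueError(f"{record.specimen_id}: TMJ and bite point coincide")
    return BiteForceResult(record.specimen_id, TCS, MCS, t, m, Mo)


def bite_force_table(dataset: AnnotatedDataset,
                     roles: BiteForceRoleMap = BiteForceRoleMap()) -> pd.DataFrame:
    """Per-specimen BF table with site/diet/sex annotations."""
    site_map = dataset.site_by_name
    rows = []
    for r in dataset.specimens:
        bf = estimate_bite_force(r, roles)
        rows.append(
            {
                "specimen_id": r.specimen_id,
                "site": r.site,
                "diet_group": site_map[r.site].diet_group if r.site else "",
                "sex": r.sex,
                "TCS": bf.TCS, "MCS": bf.MCS, "t": bf.t, "m": bf.m,
                "Mo": bf.Mo, "BF": bf.BF,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class GroupComparisonReport:
    """Univariate group-comparison pipeline output.

    ``anova_kind`` is "welch" when Levene's test rejected homogeneity
    of variance at alpha, else "classical".
    """

    groups: list[str]
    dropped_groups: list[str]
    n_per_group: dict[str, int]
    shapiro: pd.DataFrame
    levene_W: float
    levene_p: float
    anova_kind: str
    F: float
    df_between: float
    df_within: float
    p_value: float
    tukey: pd.DataFrame

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if not isinstance(v, pd.DataFrame)}
        d["shapiro"] = self.shapiro.to_dict(orient="records")
        d["tukey"] = self.tukey.to_dict(orient="records")
        return d


def compare_groups_univariate(values: Sequence[float], labels: Sequence,
                              alpha: float = 0.05,
                              posthoc: bool = True) -> GroupComparisonReport:
    """Compare a univariate measure (e.g. BF) across groups.

    Groups with fewer than two members are dropped (and recorded) since
    a variance cannot be estimated for them. The branch between Welch's
    and the classical one-way ANOVA is decided by Levene's test
    (median-centred) at ``alpha``. ``posthoc=False`` skips the Tukey HSD
    table (its studentized-range quadrature dominates runtime). The
    report is fully deterministic.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    uniq = list(pd.unique(labels))
    kept, dropped = [], []
    for gname in uniq:
        (kept if (labels == gname).sum() >= 2 else dropped).append(gname)
    if len(kept) < 2:
        raise ValueError(f"fewer than two groups with >=2 members (kept: {kept})")
    mask = np.isin(labels, kept)
    v, lab = values[mask], labels[mask]
    samples = [v[lab == gname] for gname in kept]

    shapiro_rows = []
    for gname, s in zip(kept, samples):
        if len(s) >= 3 and np.ptp(s) > 0:
            W, p = stats.shapiro(s)
        else:
            W, p = np.nan, np.nan
        shapiro_rows.append({"group": str(gname), "n": len(s), "W": W, "p": p})
    shapiro_df = pd.DataFrame(shapiro_rows)

    lev_W, lev_p = stats.levene(*samples, center="median")
    if lev_p < alpha:
        aov = pg.welch_anova(
            dv="value", between="group",
            data=pd.DataFrame({"value": v, "group": lab}),
        )
        kind = "welch"
        F = float(aov["F"].iloc[0])
        df_b = float(aov["ddof1"].iloc[0])
        df_w = float(aov["ddof2"].iloc[0])
        pcol = "p_unc" if "p_unc" in aov.columns else "p-unc"
        p_val = float(aov[pcol].iloc[0])
    else:
        F, p_val = stats.f_oneway(*samples)
        kind = "classical"
        df_b = float(len(kept) - 1)
        df_w = float(len(v) - len(kept))
        F, p_val = float(F), float(p_val)

    if posthoc:
        tk = pairwise_tukeyhsd(v, lab.astype(str), alpha=alpha)
        tukey_df = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])
    else:
        tukey_df = pd.DataFrame()

    return GroupComparisonReport(
        groups=[str(gname) for gname in kept],
        dropped_groups=[str(gname) for gname in dropped],
        n_per_group={str(gname): int(len(s)) for gname, s in zip(kept, samples)},
        shapiro=shapiro_df,
        levene_W=float(lev_W), levene_p=float(lev_p),
        anova_kind=kind, F=F, df_between=df_b, df_within=df_w, p_value=p_val,
        tukey=tukey_df,
    )
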