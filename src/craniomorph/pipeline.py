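"""Config-driven orchestration of the full analysis sequence.

The canonical order mirrors the study design: mirror-impute missing
landmarks and subset to complete specimens per landmark set; generalized
Procrustes superimposition; preliminary analyses (shape-on-size
regression, sex Procrustes ANOVA, bite-force sex ANOVA — non-significant
dimorphism justifies pooling the sexes, which is logged); diet analyses
(permutation MANOVA, CVA, pairwise Procrustes-distance tests, bite-force
group comparison); population-history analyses (site summaries and
Moran's I correlograms for centroid size and PC1/PC2).

A single global seed feeds per-stage seeds derived by hashing the stage
name, so disabling one stage never perturbs another's randomness, and
re-running an identical config reproduces every table bit-for-bit.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import plots
from .biteforce import BiteForceRoleMap, bite_force_table, compare_groups_univariate
from .io import AnnotatedDataset
from .preprocessing import impute_dataset, subset_complete
from .shape_stats import (cva, pairwise_group_distance_test,
                          procrustes_group_anova, shape_on_size_regression)
from .spatial import correlogram, great_circle_distance_matrix, site_summaries
from .superimposition import gpa
from .synthetic import generate_dataset, paper_like_simulation

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "stage_seed"]

SHAPE_SETS = ("craniofacial", "facial", "neurocranial", "temporalis")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed (stable across sessions), < 2^31."""
    return (int(global_seed) ^ zlib.crc32(stage.encode())) % (2**31 - 1)


@dataclass
class PipelineConfig:
    """What to run and at what cost.

    With no input paths, study-condition synthetic datasets are
    generated per landmark set (sharing site structure and seed).
    """

    seed: int = 0
    n_perm: int = 999
    landmark_sets: Sequence[str] = ("craniofacial", "neurocranial", "temporalis")
    run_preliminary: bool = True
    run_diet: bool = True
    run_spatial: bool = True
    run_biteforce: bool = True
    make_figures: bool = False
    out_dir: Optional[str] = None
    distance_class_km: float = 100.0
    max_missing: int = 3
    alpha: float = 0.05
    missing_rate: float = 0.02
    group_effect_norm: float = 0.03
    allometry_r2: float = 0.05
    # optional file inputs: {set_id: {"landmarks": path, "format": ...}}
    inputs: Optional[dict] = None
    specimen_table: Optional[str] = None
    site_table: Optional[str] = None


@dataclass
class RunReport:
    tables: dict = field(default_factory=dict)
    log: list = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in self.tables.items():
            if isinstance(df, pd.DataFrame):
                df.to_csv(out / f"{name}.csv")
        (out / "run_log.txt").write_text("\n".join(self.log) + "\n")
        (out / "provenance.json").write_text(json.dumps(self.provenance, indent=2))


def _synthetic_inputs(config: PipelineConfig) -> dict[str, AnnotatedDataset]:
    from .superimposition import centroid_size
    from .synthetic import allometry_norm_for_r2, make_template_skull

    datasets = {}
    wanted = list(config.landmark_sets)
    if config.run_biteforce and "biteforce" not in wanted:
        wanted.append("biteforce")
    for set_id in wanted:
        sim = paper_like_simulation(
            set_id,
            seed=stage_seed(config.seed, f"simulate:{set_id}"),
            missing_rate=0.0 if set_id == "biteforce" else config.missing_rate,
            group_effect_norm=config.group_effect_norm,
        )
        sim.allometry_norm = allometry_norm_for_r2(
            sim.template, sim.noise_sd, sim.ln_size_sd, config.allometry_r2
        )
        datasets[set_id], _ = generate_dataset(sim)
    return datasets


def _file_inputs(config: PipelineConfig) -> dict[str, AnnotatedDataset]:
    from .io import attach_metadata, read_landmark_table
    from .landmark_sets import default_set

    datasets = {}
    for set_id, entry in config.inputs.items():
        records = read_landmark_table(entry["landmarks"], entry.get("format"))
        datasets[set_id] = attach_metadata(
            records, config.site_table, default_set(set_id),
            specimen_table=config.specimen_table,
        )
    return datasets


def run_pipeline(config: PipelineConfig) -> RunReport:
    report = RunReport()
    report.provenance = {
        "seed": config.seed,
        "n_perm": config.n_perm,
        "landmark_sets": list(config.landmark_sets),
        "config": {k: v for k, v in vars(config).items()
                   if k != "out_dir"
                   and isinstance(v, (int, float, str, bool, type(None)))},
    }
    log = report.log.append

    datasets = _file_inputs(config) if config.inputs else _synthetic_inputs(config)

    # --- impute + subset, GPA per set -----------------------------------
    gpa_results, complete = {}, {}
    for set_id, ds in datasets.items():
        imputed, comp_report = impute_dataset(ds, config.max_missing)
        report.tables[f"completeness_{set_id}"] = comp_report.set_index("specimen_id")
        for _, row in comp_report[comp_report.excluded].iterrows():
            log(f"[impute:{set_id}] excluded {row.specimen_id}: "
                f"{row.n_missing_before} landmarks missing")
        ds_complete = subset_complete(imputed, ds.spec)
        kept = {r.specimen_id for r in ds_complete.specimens}
        for r in imputed.specimens:
            if r.specimen_id not in kept:
                log(f"[subset:{set_id}] dropped incomplete specimen {r.specimen_id}")
        complete[set_id] = ds_complete
        if len(ds_complete.specimens) >= 2 and set_id != "biteforce":
            gpa_results[set_id] = gpa(ds_complete.coords_array())
            log(f"[gpa:{set_id}] n={len(ds_complete.specimens)}, "
                f"iterations={gpa_results[set_id].iterations}")

    # --- preliminary -----------------------------------------------------
    if config.run_preliminary:
        rows = []
        for set_id, res in gpa_results.items():
            reg = shape_on_size_regression(
                res.tangent, np.log(res.csize), n_perm=config.n_perm,
                seed=stage_seed(config.seed, f"regression:{set_id}"),
            )
            rows.append({"landmark_set": set_id, "F": reg.F, "r2": reg.r2,
                         "pct_explained": reg.pct_explained, "p": reg.p_perm,
                         "df1": reg.df[0], "df2": reg.df[1]})
        report.tables["shape_size_regression"] = pd.DataFrame(rows).set_index("landmark_set")

        rows = []
        for set_id, res in gpa_results.items():
            sexes = np.array([r.sex for r in complete[set_id].specimens])
            counts = pd.Series(sexes).value_counts()
            keep = counts[counts >= 2].index
            mask = np.isin(sexes, keep)
            if len(keep) < 2:
                log(f"[sex_anova:{set_id}] skipped: fewer than two sexes with n>=2")
                continue
            test = procrustes_group_anova(
                res.tangent[mask], sexes[mask], n_perm=config.n_perm,
                seed=stage_seed(config.seed, f"sex_anova:{set_id}"),
            )
            rows.append({"landmark_set": set_id, "F": test.F,
                         "df_between": test.df_between, "df_within": test.df_within,
                         "p": test.p_perm})
            verdict = "non-significant; sexes pooled for subsequent analyses" \
                if test.p_perm >= config.alpha else \
                "significant; sexes pooled regardless to preserve sample size (logged)"
            log(f"[sex_anova:{set_id}] p={test.p_perm:.4f}: {verdict}")
        if rows:
            report.tables["sex_procrustes_anova"] = pd.DataFrame(rows).set_index("landmark_set")

    # --- bite force -------------------------------------------------------
    bf_df = None
    if config.run_biteforce and "biteforce" in complete:
        ds_bf = complete["biteforce"]
        if ds_bf.specimens:
            bf_df = bite_force_table(ds_bf)
            report.tables["bite_force"] = bf_df.set_index("specimen_id")
            if config.run_preliminary:
                sex_counts = bf_df.sex.value_counts()
                if (sex_counts >= 2).sum() >= 2:
                    keep = bf_df.sex.isin(sex_counts[sex_counts >= 2].index)
                    rep = compare_groups_univariate(
                        bf_df.BF[keep], bf_df.sex[keep], alpha=config.alpha)
                    report.tables["bite_force_sex_anova"] = pd.DataFrame([{
                        "kind": rep.anova_kind, "F": rep.F, "df_between": rep.df_between,
                        "df_within": rep.df_within, "p": rep.p_value,
                        "levene_p": rep.levene_p,
                    }])
                    report.tables["bite_force_sex_tukey"] = rep.tukey
            if config.run_diet:
                rep = compare_groups_univariate(bf_df.BF, bf_df.diet_group,
                                                alpha=config.alpha)
                for gname in rep.dropped_groups:
                    log(f"[biteforce] group {gname} not included in this ANOVA "
                        f"(>1 individual required per group)")
                report.tables["bite_force_diet_anova"] = pd.DataFrame([{
                    "kind": rep.anova_kind, "F": rep.F, "df_between": rep.df_between,
                    "df_within": rep.df_within, "p": rep.p_value,
                    "levene_p": rep.levene_p,
                }])
                report.tables["bite_force_diet_tukey"] = rep.tukey
                report.tables["bite_force_shapiro"] = rep.shapiro.set_index("group")

    # --- diet -------------------------------------------------------------
    if config.run_diet:
        rows = []
        for set_id, res in gpa_results.items():
            ds = complete[set_id]
            diets = ds.diet_groups()
            counts = pd.Series(diets).value_counts()
            keep = counts[counts >= 2].index
            mask = np.isin(diets, keep)
            if len(keep) >= 2:
                test = procrustes_group_anova(
                    res.tangent[mask], diets[mask], n_perm=config.n_perm,
                    seed=stage_seed(config.seed, f"diet_manova:{set_id}"),
                )
                rows.append({"landmark_set": set_id, "F": test.F,
                             "df_between": test.df_between,
                             "df_within": test.df_within, "p": test.p_perm})
                cv = cva(res.tangent[mask], diets[mask])
                report.tables[f"cva_scores_{set_id}"] = pd.DataFrame(
                    cv.cv_scores,
                    columns=[f"CV{k + 1}" for k in range(cv.n_axes)],
                    index=[r.specimen_id for r, keep_it
                           in zip(ds.specimens, mask) if keep_it],
                ).assign(diet_group=diets[mask])
                report.tables[f"cva_pct_{set_id}"] = pd.DataFrame({
                    "axis": [f"CV{k + 1}" for k in range(cv.n_axes)],
                    "pct_differentiation": cv.pct_differentiation,
                }).set_index("axis")
                if config.make_figures and config.out_dir:
                    Path(config.out_dir).mkdir(parents=True, exist_ok=True)
                    plots.cva_scatter(
                        cv.cv_scores, diets[mask], cv.pct_differentiation,
                        str(Path(config.out_dir) / f"cva_{set_id}.png"),
                        title=f"CVA: {set_id}",
                    )
            table = pairwise_group_distance_test(
                res.tangent, diets, consensus=res.consensus, n_perm=config.n_perm,
                seed=stage_seed(config.seed, f"pairwise:{set_id}"),
            )
            report.tables[f"pairwise_distances_{set_id}"] = table.to_dataframe()
        if rows:
            report.tables["diet_permutation_manova"] = (
                pd.DataFrame(rows).set_index("landmark_set"))

    # --- spatial ----------------------------------------------------------
    if config.run_spatial:
        for set_id, res in gpa_results.items():
            ds = complete[set_id]
            summaries = site_summaries(ds, res)
            report.tables[f"site_summaries_{set_id}"] = summaries.set_index("site")
            D = great_circle_distance_matrix(ds.sites)
            site_order = [s.site for s in ds.sites]
            joined = summaries.set_index("site").reindex(site_order)
            empty = joined.index[joined["csize"].isna()]
            for sname in empty:
                log(f"[spatial:{set_id}] site {sname} has no specimens; "
                    f"excluded pairwise from correlograms")
            cgs = []
            for var in ("csize", "PC1", "PC2"):
                if var not in joined.columns:
                    continue
                cg = correlogram(
                    joined[var].to_numpy(), D.to_numpy(),
                    width_km=config.distance_class_km, n_perm=config.n_perm,
                    seed=stage_seed(config.seed, f"correlogram:{set_id}:{var}"),
                    variable=f"{set_id} {var}",
                )
                cgs.append(cg)
                report.tables[f"correlogram_{set_id}_{var}"] = (
                    cg.to_dataframe().set_index("distance_class"))
            if config.make_figures and config.out_dir and cgs:
                Path(config.out_dir).mkdir(parents=True, exist_ok=True)
                plots.correlogram_biplot(
                    cgs, str(Path(config.out_dir) / f"correlogram_{set_id}.png"))
        if config.make_figures and config.out_dir and bf_df is not None:
            plots.boxplot_with_jitter(
                bf_df.BF, bf_df.diet_group,
                str(Path(config.out_dir) / "bite_force_diet.png"))

    if config.out_dir:
        report.write(config.out_dir)
    return report
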