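"""End-to-end orchestration: read → stoichiometry → vectors → diversity → drivers.

Stage order mirrors the analysis workflow: regional comparisons first, then
the vector analysis of enzyme stoichiometry, then community diversity, and
finally the driver screen (correlations, regressions, Mantel tests,
stepwise selection and permutation importance).  All result tables are
written at the end of a successful run, so a failing stage leaves no
partial outputs; the JSON manifest records the seed, configuration, stage
timings and file checksums.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    DistanceMatrix,
    DomainError,
    EEStoichError,
    Region,
    RunConfig,
)
from .diversity import distance_matrix, diversity_frame, rarefy
from .drivers import (
    anova_oneway,
    forward_stepwise,
    mantel,
    ols,
    pearson,
    permutation_importance,
)
from .io import read_otu_table, read_sample_table, records_to_frame, write_results
from .stoichiometry import acquisition_frame, cohort_summary
from .vectors import cohort_vector_summary, limitation_table

logger = logging.getLogger(__name__)

__all__ = ["PipelineError", "run_pipeline"]

#: Abiotic variables screened as drivers of the limitation statistics.
DRIVER_VARS: tuple[str, ...] = (
    "water_depth_m", "water_tds_mg_l", "water_conductivity", "sed_tc_g_kg",
)
#: Wider candidate pool for stepwise selection.
CANDIDATE_VARS: tuple[str, ...] = DRIVER_VARS + (
    "water_ph", "water_salinity", "sed_ph", "sed_doc",
)
#: Variables compared between regions by one-way ANOVA.
ANOVA_VARS: tuple[str, ...] = (
    "bg", "cbh", "nag", "lap", "ap",
    "water_depth_m", "water_tds_mg_l", "water_conductivity", "water_ph",
    "sed_tc_g_kg", "sed_tn_g_kg", "sed_tp_g_kg", "sed_doc", "sed_ph",
)


class PipelineError(EEStoichError):
    """A stage failed; the message names the stage."""


def _abs_diff_matrix(values: pd.Series, ids: list[str]) -> DistanceMatrix:
    v = values.to_numpy(dtype=float)
    return DistanceMatrix(ids=ids, d=np.abs(v[:, None] - v[None, :]))


def _subset_dm(dm: DistanceMatrix, ids: list[str]) -> DistanceMatrix:
    idx = [dm.ids.index(i) for i in ids]
    return DistanceMatrix(ids=ids, d=dm.d[np.ix_(idx, idx)])


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the full analysis; returns the run manifest."""
    timings: dict[str, float] = {}
    warnings: list[str] = []
    tables: dict[str, pd.DataFrame] = {}
    summary: dict = {}

    def stage(name):
        class _Timer:
            def __enter__(self_):
                self_.t0 = time.perf_counter()
                return self_

            def __exit__(self_, exc_type, exc, tb):
                timings[name] = round(time.perf_counter() - self_.t0, 4)
                if exc is not None and not isinstance(exc, PipelineError):
                    raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return _Timer()

    # ------------------------------------------------------------- read
    with stage("read"):
        if not cfg.samples_path:
            raise DomainError("no samples_path configured")
        records = read_sample_table(cfg.samples_path)
        frame = records_to_frame(records)
        frame = frame.set_index("sample_id", drop=False)

    # ---------------------------------------------- stoichiometry+vectors
    with stage("vectors"):
        vec = limitation_table(records, cfg)
        tables["vector_results"] = vec
        tables["stoichiometry"] = acquisition_frame(records, cfg.ln_transform)
        st = cohort_summary(records)
        summary["stoichiometry"] = {
            "mean_c": st.mean_c, "mean_n": st.mean_n, "mean_p": st.mean_p,
            "ratio_c_n_p": [1.0, round(st.ratio_n_to_c, 2), round(st.ratio_p_to_c, 2)],
            "mean_ratio_n_to_c": st.mean_ratio_n_to_c,
            "mean_ratio_p_to_c": st.mean_ratio_p_to_c,
        }
        summary["vectors"] = cohort_vector_summary(vec, cfg.angle_threshold_deg)
        vl = vec.set_index("sample_id")["length"]
        va = vec.set_index("sample_id")["angle_deg"]

    # --------------------------------------------------------- diversity
    div_tables: dict[str, object] = {}
    with stage("diversity"):
        for domain, otu_path, tax_path in (
            ("bacteria", cfg.otu_bacteria_path, cfg.taxonomy_bacteria_path),
            ("fungi", cfg.otu_fungi_path, cfg.taxonomy_fungi_path),
        ):
            if not otu_path or not tax_path:
                warnings.append(f"no {domain} OTU table configured; stage skipped")
                continue
            table = read_otu_table(otu_path, tax_path)
            depths = table.sample_depths()
            depth = int(depths[depths > 0].min())
            rare = rarefy(table, depth, seed=cfg.seed)
            tables[f"diversity_{domain}"] = diversity_frame(rare)
            dm = distance_matrix(rare)
            mat = pd.DataFrame(dm.d, columns=dm.ids)
            mat.insert(0, "sample_id", dm.ids)
            tables[f"bray_curtis_{domain}.tsv"] = mat
            div_tables[domain] = (rare, dm, depth)
            summary[f"rarefaction_depth_{domain}"] = depth

    # ------------------------------------------------------------- anova
    with stage("anova"):
        region_groups = frame.groupby("region")
        shannon_cols = {}
        for domain in div_tables:
            sh = tables[f"diversity_{domain}"].set_index("sample_id")["shannon"]
            shannon_cols[f"shannon_{domain}"] = frame["sample_id"].map(sh)
        anova_frame = frame.assign(**shannon_cols)
        n_regions = frame["region"].nunique()
        rows = []
        if n_regions < 2:
            warnings.append("single-region cohort; between-region ANOVA skipped")
        else:
            for var in list(ANOVA_VARS) + list(shannon_cols):
                groups = [g[var].dropna().to_numpy()
                          for _, g in anova_frame.groupby("region")]
                try:
                    res = anova_oneway(groups)
                except DomainError as err:
                    warnings.append(f"ANOVA skipped for {var}: {err}")
                    continue
                rows.append({
                    "variable": var, "f_stat": res.f_stat,
                    "df_between": res.df_between, "df_within": res.df_within,
                    "p_value": res.p_value,
                })
        tables["anova_regions"] = pd.DataFrame(rows)

    # ----------------------------------------------------------- drivers
    with stage("drivers"):
        corr_rows = []
        for stat_name, stat in (("VL", vl), ("VA", va)):
            for var in DRIVER_VARS:
                xs = frame[var].astype(float)
                try:
                    r, p = pearson(xs, stat.reindex(frame.index),
                                   x_name=var, y_name=stat_name)
                except DomainError as err:
                    warnings.append(f"correlation skipped ({stat_name}~{var}): {err}")
                    continue
                n_pairs = int((np.isfinite(xs) & np.isfinite(stat.reindex(frame.index))).sum())
                corr_rows.append({"statistic": stat_name, "variable": var,
                                  "r": r, "p": p, "n": n_pairs})
        tables["correlations"] = pd.DataFrame(corr_rows)

        # VA on VL: the within-cohort coupling of nutrient vs carbon limitation
        ok = vl.notna() & va.notna()
        if ok.sum() > 2 and vl[ok].nunique() > 1:
            fit = ols(va[ok], pd.DataFrame({"VL": vl[ok]}))
            summary["va_on_vl"] = {
                "slope": fit.coefficients["VL"], "adj_r2": fit.adj_r2,
                "p": fit.p_values["VL"], "n": fit.n,
            }

        X = frame.loc[ok[ok].index, list(CANDIDATE_VARS)].astype(float)
        step_results = {}
        for stat_name, stat in (("VL", vl[ok]), ("VA", va[ok])):
            model = forward_stepwise(stat, X)
            step_results[stat_name] = {
                "selected": model.predictors,
                "coefficients": model.coefficients,
                "intercept": model.intercept,
                "adj_r2": model.adj_r2,
                "aic": model.aic,
                "n": model.n,
            }
            if model.predictors:
                imp = permutation_importance(model, stat, X, n_rep=100, seed=cfg.seed)
                imp.insert(0, "statistic", stat_name)
                key = f"importance_{stat_name.lower()}"
                tables[key] = imp
        summary["stepwise"] = step_results

        mantel_rows = []
        for domain, (rare, dm, _) in div_tables.items():
            common = [s for s in dm.ids if s in vl.index and np.isfinite(vl[s])]
            if len(common) < 4:
                warnings.append(f"too few shared samples for Mantel ({domain})")
                continue
            dm_c = _subset_dm(dm, common)
            for stat_name, stat in (("VL", vl), ("VA", va)):
                delta = _abs_diff_matrix(stat.loc[common], common)
                res = mantel(dm_c, delta, n_perm=cfg.n_permutations, seed=cfg.seed)
                mantel_rows.append({
                    "matrix1": f"bray_curtis_{domain}",
                    "matrix2": f"abs_diff_{stat_name}",
                    "r": res.r_obs, "p": res.p_value,
                    "n_perm": res.n_perm, "n": res.n,
                })
        tables["mantel"] = pd.DataFrame(mantel_rows)

    # ------------------------------------------------------------- write
    with stage("write"):
        outdir = Path(cfg.outdir)
        manifest = write_results(
            tables, outdir, config=cfg.to_dict(), seed=cfg.seed,
            extra={"timings_s": timings, "warnings": warnings, "summary": summary},
        )
        (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return manifest
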