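"""Pipeline orchestration and publication-style CSV renderers.

``run_pipeline`` executes the full analysis on a cohort (read from CSV or
drawn from the synthetic generator): reference labeling, descriptive group
comparisons, per-biomarker logistic models and ROC/cut-off reports,
all-pairs DeLong AUC comparisons with FDR control, dual rule-in/rule-out
cut-offs for the pTau markers, MMSE linear models, and the measurement-noise
robustness simulation.  Each stage emits a CSV rendered at the precision
used in the study's tables (effect sizes to 1 decimal, AUC/SE/SP to 3,
PPV/NPV to 2), plus a JSON run manifest with the seed and per-stage counts.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__
from .cohort import (CSF_AB42_40_STANDARD, CSF_AB42_PTAU_STANDARD, CSF_MARKERS,
                     PLASMA_MARKERS, CohortTable, DERIVED_RATIOS,
                     ReferenceStandard, label_cohort, read_cohort, split_groups)
from .compare import chi_square_categorical, compare_all
from .models import logistic_biomarker_model, mmse_linear_model
from .robustness import DEFAULT_CV_GRID, robustness_curve, robustness_verdict
from .roc import auc_comparison_matrix, roc_curve, two_cutoffs, youden_cutoff, auc_mann_whitney

__all__ = ["PipelineConfig", "run_pipeline", "render_table"]

log = logging.getLogger("bbadkit")

TABLE2_MARKERS = (["csf_ab42", "csf_ab40", "csf_ttau", "csf_ptau181",
                   "csf_ab42_40", "csf_ab42_ttau", "csf_ab42_ptau"]
                  + PLASMA_MARKERS)
# the label-defining CSF Abeta42/40 ratio is excluded from ROC/logistic
# stages (it would be compared against itself)
ROC_MARKERS = CSF_MARKERS + PLASMA_MARKERS

_REFERENCES = {
    "csf_ab42_40": CSF_AB42_40_STANDARD,
    "csf_ab42_ptau": CSF_AB42_PTAU_STANDARD,
}


@dataclass
class PipelineConfig:
    """Everything one run needs; exactly one of csv_path / generator_config."""

    csv_path: str | None = None
    generator_config: object | None = None   # simulate.GeneratorConfig
    reference: str = "csf_ab42_40"   # or "csf_ab42_ptau", or a ReferenceStandard
    subset: str = "all"              # "all" | "MCI"
    prevalence: float | None = None  # override for PPV/NPV; default sample
    cv_grid: tuple = DEFAULT_CV_GRID
    replicates: int = 500
    seed: int = 0
    fdr_method: str = "BH"
    outdir: str | Path = "bbadkit_reports"

    def standard(self) -> ReferenceStandard:
        if isinstance(self.reference, ReferenceStandard):
            return self.reference
        try:
            return _REFERENCES[self.reference]
        except KeyError:
            raise ValueError(f"unknown reference standard {self.reference!r}")


def _round_df(df: pd.DataFrame, digits: dict[str, int]) -> pd.DataFrame:
    out = df.copy()
    for col, nd in digits.items():
        if col in out.columns:
            out[col] = out[col].map(
                lambda v: "" if pd.isna(v) else f"{v:.{nd}f}")
    return out


_STYLES = {
    "table1": {"p": 3, "mean_neg": 1, "sd_neg": 1, "mean_pos": 1, "sd_pos": 1},
    "table2": {"mean_neg": 2, "sd_neg": 2, "mean_pos": 2, "sd_pos": 2,
               "pct_median_diff": 1, "d": 1, "d_ci_low": 1, "d_ci_high": 1,
               "p_raw": 4, "p_adjusted_age_sex": 4, "p_fdr": 4,
               "p_bonferroni": 4},
    "table3": {"st_coefficient": 2, "p": 4, "cutoff": 3, "auc": 3,
               "auc_ci_low": 3, "auc_ci_high": 3, "sensitivity": 3,
               "specificity": 3, "ppv": 2, "npv": 2},
    "table4": None,   # symmetric p matrix, 3 decimals
    "table5": {"coefficient": 3, "se": 3, "p": 3, "model_p": 4},
    "fig4": {"cutoff": 3, "sensitivity": 3, "specificity": 3, "ppv": 2,
             "npv": 2, "intermediate_fraction": 3},
    "robustness": {"cv": 3, "mean_auc": 3, "sd_auc": 3, "auc_drop": 3},
}


def render_table(result: pd.DataFrame, style: str) -> str:
    """Render a stage result as CSV text at the study's printed precision."""
    if style not in _STYLES:
        raise ValueError(f"unknown style {style!r}")
    if not isinstance(result, pd.DataFrame):
        raise TypeError(f"render_table expects a DataFrame for style {style!r}")
    if style == "table4":
        out = result.round(3)
        return out.to_csv(index=True)
    return _round_df(result, _STYLES[style]).to_csv(index=False)


def _table1(cohort: CohortTable) -> pd.DataFrame:
    rows = []
    for var in ("age", "education", "mmse"):
        neg, pos = split_groups(cohort, var)
        neg, pos = neg[~np.isnan(neg)], pos[~np.isnan(pos)]
        p = stats.ttest_ind(pos, neg, equal_var=False).pvalue
        rows.append({"variable": var, "kind": "continuous",
                     "mean_neg": neg.mean(), "sd_neg": neg.std(ddof=1),
                     "mean_pos": pos.mean(), "sd_pos": pos.std(ddof=1),
                     "p": p})
    for var in ("sex", "apoe_e4", "diagnosis"):
        rows.append({"variable": var, "kind": "categorical",
                     "mean_neg": np.nan, "sd_neg": np.nan,
                     "mean_pos": np.nan, "sd_pos": np.nan,
                     "p": chi_square_categorical(cohort, var)})
    return pd.DataFrame(rows)


def _table3(cohort: CohortTable, prevalence: float | None) -> pd.DataFrame:
    rows = []
    labels = cohort.df["a_positive"].to_numpy()
    specs = [(b, False) for b in ROC_MARKERS] + [("plasma_ab42_40", True)]
    for biomarker, excl in specs:
        logi = logistic_biomarker_model(cohort, biomarker, exclude_outliers=excl)
        scores = cohort.df[biomarker].to_numpy(dtype=float)
        if excl:
            mu, sd = scores.mean(), scores.std(ddof=1)
            keep = np.abs(scores - mu) <= 3.0 * sd
            scores_used, labels_used = scores[keep], labels[keep]
        else:
            scores_used, labels_used = scores, labels
        curve = roc_curve(scores_used, labels_used)
        auc = auc_mann_whitney(curve.scores_oriented, labels_used)
        rep = youden_cutoff(curve, prevalence)
        rows.append({
            "biomarker": biomarker + ("*" if excl else ""),
            "st_coefficient": logi.standardized_coefficient,
            "p": logi.p,
            "cutoff": rep.cutoff,
            "orientation": rep.orientation,
            "auc": auc.auc, "auc_ci_low": auc.ci95_low,
            "auc_ci_high": auc.ci95_high,
            "sensitivity": rep.sensitivity, "specificity": rep.specificity,
            "ppv": rep.ppv, "npv": rep.npv,
            "n_used": logi.n_used, "outliers_excluded": logi.outliers_excluded,
        })
    return pd.DataFrame(rows)


def _fig4(cohort: CohortTable, prevalence: float | None) -> pd.DataFrame:
    rows = []
    labels = cohort.df["a_positive"].to_numpy()
    for biomarker in ("plasma_ptau181", "plasma_ptau217"):
        curve = roc_curve(cohort.df[biomarker].to_numpy(dtype=float), labels)
        rep = two_cutoffs(curve, prevalence=prevalence)
        for role, cut in (("rule_in", rep.rule_in), ("rule_out", rep.rule_out)):
            rows.append({
                "biomarker": biomarker, "role": role,
                "cutoff": np.nan if cut is None else cut.cutoff,
                "sensitivity": np.nan if cut is None else cut.sensitivity,
                "specificity": np.nan if cut is None else cut.specificity,
                "ppv": np.nan if cut is None else cut.ppv,
                "npv": np.nan if cut is None else cut.npv,
                "intermediate_fraction": rep.intermediate_fraction,
            })
    return pd.DataFrame(rows)


def _table5(cohort: CohortTable) -> pd.DataFrame:
    frames = []
    for biomarker in PLASMA_MARKERS:
        res = mmse_linear_model(cohort, biomarker)
        t = res.terms.copy()
        t.insert(0, "biomarker", biomarker)
        t["model_p"] = res.model_p
        t["n_used"] = res.n_used
        frames.append(t[["biomarker", "term", "coefficient", "se", "p",
                         "model_p", "n_used"]])
    return pd.concat(frames, ignore_index=True)


def _robustness(cohort: CohortTable, cfg: PipelineConfig) -> pd.DataFrame:
    df = cohort.df
    labels = df["a_positive"].to_numpy()
    rows = []
    for biomarker in PLASMA_MARKERS:
        parts = None
        scores = df[biomarker].to_numpy(dtype=float)
        if biomarker in DERIVED_RATIOS:
            num, den = DERIVED_RATIOS[biomarker]
            parts = (df[num].to_numpy(dtype=float), df[den].to_numpy(dtype=float))
        curve = robustness_curve(scores, labels, cv_grid=cfg.cv_grid,
                                 replicates=cfg.replicates, seed=cfg.seed,
                                 name=biomarker, ratio_parts=parts)
        verdict = robustness_verdict(curve)
        for cv, ma, sa in zip(curve.cv_grid, curve.mean_auc, curve.sd_auc):
            rows.append({"biomarker": biomarker, "cv": cv, "mean_auc": ma,
                         "sd_auc": sa, "replicates": curve.replicates,
                         "seed": curve.seed, "auc_drop": curve.auc_drop,
                         "verdict": verdict.verdict})
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the report bundle; returns the results.

    The bundle contains table1.csv ... table5.csv, two_cutoffs.csv,
    robustness.csv and manifest.json.  Two runs with the same configuration
    and seed produce byte-identical bundles.
    """
    if config.csv_path is not None and config.generator_config is not None:
        raise ValueError("give either csv_path or generator_config, not both")
    if config.csv_path is None and config.generator_config is None:
        from .simulate import default_config
        config.generator_config = default_config()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.StreamHandler(sys.stderr)
    log.addHandler(handler)
    manifest: dict = {"seed": config.seed, "version": __version__,
                      "subset": config.subset,
                      "reference": config.standard().measure, "stages": {}}
    results: dict = {}
    stage = "load"
    try:
        if config.csv_path is not None:
            cohort = read_cohort(config.csv_path)
            manifest["input"] = str(config.csv_path)
        else:
            from .simulate import generate_cohort
            cohort = generate_cohort(config.generator_config, seed=config.seed)
            manifest["input"] = "generator"
        manifest["stages"]["load"] = {
            "rows_in": len(cohort) + cohort.n_excluded,
            "excluded": cohort.n_excluded, "analyzed": len(cohort)}

        stage = "label"
        labeled = label_cohort(cohort, config.standard(), subset=config.subset)
        prevalence = config.prevalence
        manifest["stages"]["label"] = {
            "rows_in": len(cohort),
            "excluded": len(cohort) - len(labeled),
            "analyzed": len(labeled),
            "n_pos": int(labeled.df["a_positive"].sum()),
            "n_neg": int((1 - labeled.df["a_positive"]).sum()),
        }

        for stage, builder, style, fname in (
                ("table1", _table1, "table1", "table1.csv"),
                ("table2", lambda c: compare_all(c, TABLE2_MARKERS),
                 "table2", "table2.csv"),
                ("table3", lambda c: _table3(c, prevalence),
                 "table3", "table3.csv"),
                ("table4", lambda c: auc_comparison_matrix(c, PLASMA_MARKERS)[0],
                 "table4", "table4.csv"),
                ("fig4", lambda c: _fig4(c, prevalence), "fig4",
                 "two_cutoffs.csv"),
                ("table5", _table5, "table5", "table5.csv"),
                ("robustness", lambda c: _robustness(c, config), "robustness",
                 "robustness.csv")):
            if stage == "table5" and labeled.df["diagnosis"].nunique() < 2:
                # MMSE models need both diagnosis strata (MCI-only subset)
                manifest["stages"]["table5"] = {
                    "rows_in": len(labeled), "excluded": len(labeled),
                    "analyzed": 0, "skipped": "single diagnosis stratum"}
                continue
            log.info("stage %s", stage)
            result = builder(labeled)
            results[stage] = result
            (outdir / fname).write_text(render_table(result, style))
            manifest["stages"][stage] = {
                **manifest["stages"].get(stage, {}),
                "rows_in": len(labeled), "excluded": 0,
                "analyzed": len(labeled), "output": fname}
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True))
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    finally:
        log.removeHandler(handler)
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True))
    results["cohort"] = labeled
    results["manifest"] = manifest
    return results
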