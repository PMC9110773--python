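"""End-to-end orchestration: per-study mass computation, agreement tables
against a reference, accuracy ranking, and deterministic CSV reports.

Two agreement tables are produced, mirroring the two-stage reporting of a
feasibility-limited cohort: one over all subjects per method (each method
uses every subject where it was computable) and one restricted to the
complete cases (subjects where every method was computable).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .agreement import PairedSeries, percent_differences, rank_accuracy, summarize
from .errors import AnalysisError
from .io import RunConfig, StudyMeasurements, read_study
from .methods import METHODS, MethodConfig, quantify_all

log = logging.getLogger("lvmass")

_FLOAT_FMT = "%.6f"


def _method_config(cfg: RunConfig) -> MethodConfig:
    return MethodConfig(density=cfg.density, n_disks=cfg.n_disks)


def compute_cohort(studies: Iterable[StudyMeasurements],
                   cfg: RunConfig = RunConfig()) -> pd.DataFrame:
    """Run all five methods on every study.

    Returns a tidy frame with one row per (study, method):
    ``study_id, method, mass_g, t_cm, edv_endo_ml, edv_epi_ml, feasible``.
    """
    mcfg = _method_config(cfg)
    rows = []
    for study in studies:
        for res in quantify_all(study, mcfg):
            inter = res.intermediates
            rows.append({
                "study_id": study.study_id,
                "method": res.method,
                "mass_g": res.mass if res.feasible else np.nan,
                "t_cm": inter.get("t_cm", np.nan),
                "edv_endo_ml": inter.get("edv_endo_ml", np.nan),
                "edv_epi_ml": inter.get("edv_epi_ml", np.nan),
                "feasible": bool(res.feasible),
            })
    return pd.DataFrame(rows)


def load_cohort(cohort_dir: Union[str, Path]) -> list[StudyMeasurements]:
    """Read every study JSON in a directory (sorted by filename)."""
    paths = sorted(Path(cohort_dir).glob("*.json"))
    if not paths:
        raise AnalysisError(f"no study JSON files found in {cohort_dir}")
    return [read_study(p) for p in paths]


def _paired(results: pd.DataFrame, truth: pd.Series, method: str,
            subjects: Optional[Sequence[str]] = None) -> Optional[PairedSeries]:
    sub = results[(results.method == method) & results.feasible].dropna(subset=["mass_g"])
    sub = sub[sub.study_id.isin(truth.index)]
    if subjects is not None:
        sub = sub[sub.study_id.isin(subjects)]
    if len(sub) < 3:
        return None
    ids = tuple(sub.study_id)
    return PairedSeries(ids, sub.mass_g.to_numpy(), truth.loc[list(ids)].to_numpy())


def agreement_table(results: pd.DataFrame, truth: pd.Series,
                    subjects: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """One agreement row per method versus the reference masses.

    Columns mirror the accuracy-table layout: mean +/- SD of the method,
    bias +/- 95% LOA, CV %, SEE, Pearson r and p, paired-t p,
    proportional-bias slope and p.
    """
    rows = []
    for method in METHODS:
        s = _paired(results, truth, method, subjects)
        if s is None:
            continue
        a = summarize(s)
        rows.append({
            "method": method, "n": a.n,
            "mean_g": float(np.mean(s.predicted)),
            "sd_g": float(np.std(s.predicted, ddof=1)),
            "bias_g": a.bias, "loa_half_width_g": a.loa_half_width,
            "cv_pct": a.cv_pct, "see_g": a.see,
            "pearson_r": a.pearson_r, "pearson_p": a.pearson_p,
            "paired_t_p": a.paired_t_p,
            "prop_bias_slope": a.prop_bias_slope, "prop_bias_p": a.prop_bias_p,
        })
    return pd.DataFrame(rows)


def complete_case_ids(results: pd.DataFrame, truth: pd.Series) -> list[str]:
    """Subjects for which every method was feasible (and truth is known)."""
    ok = results.groupby("study_id").feasible.all()
    return sorted(set(ok[ok].index) & set(truth.index))


def run_pipeline(cohort_dir: Union[str, Path],
                 truth_csv: Optional[Union[str, Path]] = None,
                 cfg: RunConfig = RunConfig(),
                 out_dir: Optional[Union[str, Path]] = None) -> dict:
    """Full analysis of a cohort directory.

    Reads every study JSON, computes all methods, and — when a truth CSV
    (``study_id, true_mass_g``) is given — produces the all-subjects and
    complete-case agreement tables, the per-subject percentage differences
    and the most/least-accurate ranking.  With ``out_dir`` the frames are
    written as CSV with a fixed float format, so identical inputs and
    config yield byte-identical files.
    """
    log.info("run_pipeline: cohort=%s cfg=%s", cohort_dir, cfg)
    studies = load_cohort(cohort_dir)
    if len(studies) < 3:
        raise AnalysisError(f"need >= 3 studies, got {len(studies)}")
    results = compute_cohort(studies, cfg)
    out = {"results": results}

    if truth_csv is not None:
        truth_df = pd.read_csv(truth_csv)
        for col in ("study_id", "true_mass_g"):
            if col not in truth_df.columns:
                raise AnalysisError(f"truth CSV is missing column {col!r}")
        truth = truth_df.set_index("study_id").true_mass_g.astype(float)

        out["agreement_all"] = agreement_table(results, truth)
        cc = complete_case_ids(results, truth)
        if len(cc) >= 3:
            out["agreement_complete_cases"] = agreement_table(results, truth, cc)
            series = {m: s for m in METHODS
                      if (s := _paired(results, truth, m, cc)) is not None}
            if len(series) >= 2:
                rank = rank_accuracy(series, complete_cases_only=True)
                rank_rows = [{"method": m,
                              "most_accurate_count": rank["most_accurate"][m]["count"],
                              "most_accurate_pct": rank["most_accurate"][m]["pct"],
                              "least_accurate_count": rank["least_accurate"][m]["count"],
                              "least_accurate_pct": rank["least_accurate"][m]["pct"]}
                             for m in series]
                out["ranking"] = pd.DataFrame(rank_rows)
                pct_rows = []
                for m, s in series.items():
                    for sid, pct in zip(s.subject_ids, percent_differences(s)):
                        pct_rows.append({"study_id": sid, "method": m,
                                         "pct_difference": pct})
                out["percent_differences"] = pd.DataFrame(pct_rows)
        else:
            log.warning("fewer than 3 complete cases; subgroup tables skipped")

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name, df in out.items():
            df.to_csv(out_dir / f"{name}.csv", index=False, float_format=_FLOAT_FMT)
        log.info("wrote %d report files to %s", len(out), out_dir)
    return out
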