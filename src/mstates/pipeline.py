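"""End-to-end orchestration: synth -> preproc -> microstates -> stats -> classify.

:func:`run_pipeline` executes the whole analysis on a synthetic cohort (or
pre-loaded recordings), writing tidy CSV tables, a human-readable report
mirroring the group-comparison / correlation / classification summaries,
and a provenance JSON (versions, seeds, thresholds) so every output is
regenerable from config + seed alone.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import (
    crossvalidate_tree,
    evaluate_classifier,
    feature_columns,
    split_train_test,
)
from .clustering import (
    TemplateSet,
    aahc_cluster,
    align_and_average_templates,
    compute_gev,
    find_gfp_peaks,
    select_k,
)
from .config import PipelineConfig, stage_seed
from .errors import DataQualityError
from .layout import make_layout
from .preproc import PreprocResult, Recording, preprocess
from .segmentation import backfit, compute_metrics, metrics_table, segment_runs
from .stats import chi_square_2x2, compare_groups, partial_rank_correlation, \
    stepwise_regression
from .synth import CohortSpec, DynamicsSpec, make_templates, simulate_cohort

log = logging.getLogger("mstates")

#: FDR families for the group comparison, following the conventional blocks
#: of a microstate report (global rows, durations, occurrences, coverages,
#: transition probabilities).  The family partition changes adjusted p and
#: is therefore configurable and recorded in the provenance.
def default_families(class_labels: tuple[str, ...] = ("A", "B", "C", "D")) -> dict:
    return {
        "global": ["gev", "total_time"],
        "duration": [f"duration_{c}" for c in class_labels] + ["mean_duration"],
        "occurrence": [f"occurrence_{c}" for c in class_labels] + ["mean_occurrence"],
        "coverage": [f"coverage_{c}" for c in class_labels],
        "transition": [f"tp_{a}_{b}" for a in class_labels
                       for b in class_labels if a != b],
    }


@dataclass
class SubjectResult:
    subject_id: str
    group: str
    preproc: PreprocResult
    templates: TemplateSet
    selected_k: int


@dataclass
class PipelineReport:
    """Everything :func:`run_pipeline` computes, before serialization."""

    metrics: pd.DataFrame
    covariates: pd.DataFrame
    group_templates: TemplateSet
    selected_ks: list[int]
    stat_table: pd.DataFrame
    correlations: pd.DataFrame
    regression: object
    classification: object
    cv_scores: np.ndarray
    sex_chi2: tuple[float, float, int]


def analyze_subject(result: PreprocResult, cfg: PipelineConfig):
    """Per-subject clustering: GFP peaks -> AAHC -> k selection."""
    ms = cfg.microstates
    peaks = find_gfp_peaks(result.narrow, min_separation=ms.min_peak_separation)
    cr = aahc_cluster(peaks, k_min=ms.k_min, k_max=ms.k_max)
    k = ms.force_k if ms.force_k is not None else select_k(cr, ms.gev_gain_threshold)
    if k not in cr.templates:
        k = min(cr.templates, key=lambda kk: abs(kk - k))
    return peaks, cr, k


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path | None = None,
                 recordings: list[tuple[str, str, Recording]] | None = None,
                 covariates: pd.DataFrame | None = None) -> PipelineReport:
    """Run the full analysis and write the report bundle.

    ``recordings`` (subject_id, group, Recording) and ``covariates`` may be
    supplied to analyze external data; otherwise the synthetic cohort from
    ``cfg.synth`` is generated.
    """
    cfg.validate()
    out = Path(out_dir if out_dir is not None else cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- synth ------------------------------------------------------------
    if recordings is None:
        sc = cfg.synth
        spec = CohortSpec(n_per_group=(sc.n_ad, sc.n_hc),
                          group_effects={sc.group_dwell_shift_class:
                                         sc.group_dwell_shift_s},
                          seed=stage_seed(cfg.seed, "synth"))
        dyn = DynamicsSpec(k=sc.k, mean_dwell=sc.mean_dwell,
                           dwell_dispersion=sc.dwell_dispersion)
        layout = make_layout(sc.n_channels)
        templates = make_templates(layout, sc.k, seed=stage_seed(cfg.seed, "synth"))
        subjects, covariates = simulate_cohort(
            spec, layout=layout, templates=templates, dyn=dyn,
            duration_s=sc.duration_s, sfreq=sc.sfreq, snr=sc.snr,
            osc_freq=sc.osc_freq)
        recordings = [(s.subject_id, s.group, s.recording) for s in subjects]
        log.info("simulated %d subjects (%d AD / %d HC)", len(subjects),
                 sc.n_ad, sc.n_hc)
    if covariates is None:
        raise DataQualityError("covariate table required for external recordings")

    # --- preproc + per-subject clustering ----------------------------------
    pc = cfg.preproc
    per_subject = []
    individual_sets: list[TemplateSet] = []
    selected_ks: list[int] = []
    for subject_id, group, rec in recordings:
        res = preprocess(rec, band=pc.band, notch=pc.notch,
                         target_sfreq=pc.target_sfreq, epoch_s=pc.epoch_s,
                         amp_thresh=pc.amp_thresh, flat_thresh=pc.flat_thresh,
                         neighbor_z=pc.neighbor_z,
                         microstate_band=cfg.microstates.band)
        log.info("%s: %d/%d epochs kept, bad channels: %s", subject_id,
                 res.broad.n_kept, res.broad.n_epochs,
                 res.broad.bad_channels or "none")
        peaks, cr, k = analyze_subject(res, cfg)
        selected_ks.append(k)
        per_subject.append((subject_id, group, res, peaks, cr))

    # group-level k: the override if given, else the median of the
    # per-subject selections (the clinical convention is to fix k cohort-wide)
    if cfg.microstates.force_k is not None:
        group_k = cfg.microstates.force_k
    else:
        group_k = int(np.median(selected_ks))
    for _, _, _, _, cr in per_subject:
        if group_k in cr.templates:
            individual_sets.append(cr.templates[group_k])
    layout0 = recordings[0][2].layout
    group_templates = align_and_average_templates(
        individual_sets, layout=layout0 if group_k == 4 else None)

    # --- backfitting and metrics -------------------------------------------
    rows = []
    for subject_id, group, res, peaks, cr in per_subject:
        ls = backfit(res.narrow, group_templates,
                     min_segment_ms=cfg.microstates.min_segment_ms)
        rl = segment_runs(ls)
        kept = res.narrow.kept()
        centered = kept - kept.mean(axis=1, keepdims=True)
        flat_maps = centered.transpose(0, 2, 1).reshape(-1, centered.shape[1])
        gfp = np.sqrt(np.mean(flat_maps**2, axis=1))
        gev = compute_gev(flat_maps, gfp, group_templates, ls.labels.ravel())
        m = compute_metrics(rl, gev=gev, class_labels=group_templates.class_labels)
        rows.append((subject_id, group, m))
    metrics = metrics_table(rows)

    # --- statistics ---------------------------------------------------------
    merged = metrics.merge(covariates, on=["subject", "group"], how="left")
    families = default_families(group_templates.class_labels)
    feature_cols = feature_columns(group_templates.class_labels)
    stat_table = compare_groups(metrics.drop(columns=["subject"]),
                                grouping="group", families=families)

    sex_counts = pd.crosstab(covariates["group"], covariates["sex"])
    sex_chi2 = chi_square_2x2(sex_counts.to_numpy()) if sex_counts.shape == (2, 2) \
        else (float("nan"), float("nan"), 1)

    st = cfg.stats
    ad = merged[merged["group"] == "AD"]
    cov_design = pd.DataFrame({
        "sex": (ad["sex"] == "M").astype(float),
        "age": ad["age"].astype(float),
        "education": ad["education"].astype(float),
    })
    corr_rows = []
    for metric in st.correlation_metrics:
        if metric not in ad.columns:
            continue
        for target in st.correlation_targets:
            if target not in ad.columns or ad[target].isna().all():
                continue
            try:
                r = partial_rank_correlation(
                    ad[metric].to_numpy(dtype=float),
                    ad[target].to_numpy(dtype=float),
                    cov_design, covariate_names=tuple(cov_design.columns))
            except Exception as exc:  # insufficient n etc.
                log.warning("correlation %s ~ %s skipped: %s", metric, target, exc)
                continue
            corr_rows.append({"metric": metric, "covariate": target,
                              "rho": r.rho, "p": r.p, "n": r.n})
    correlations = pd.DataFrame(corr_rows)

    reg_cols = [m for m in st.correlation_metrics if m in ad.columns]
    reg_X = ad[reg_cols + ["age", "education"]].astype(float)
    reg_X = reg_X.assign(sex=(ad["sex"] == "M").astype(float))
    regression = stepwise_regression(
        ad[st.regression_outcome].to_numpy(dtype=float), reg_X,
        p_enter=st.p_enter, p_remove=st.p_remove)

    # --- classification -----------------------------------------------------
    clf_seed = stage_seed(cfg.seed, "classify")
    features = metrics[["subject", "group"] + feature_cols].dropna()
    train, test = split_train_test(features, test_fraction=cfg.classify.test_fraction,
                                   seed=clf_seed)
    cv_scores, tree = crossvalidate_tree(train, feature_cols,
                                         folds=cfg.classify.folds, seed=clf_seed)
    classification = evaluate_classifier(tree, test, feature_cols)

    report = PipelineReport(
        metrics=metrics, covariates=covariates, group_templates=group_templates,
        selected_ks=selected_ks, stat_table=stat_table, correlations=correlations,
        regression=regression, classification=classification,
        cv_scores=cv_scores, sex_chi2=sex_chi2,
    )
    _write_bundle(report, cfg, out)
    return report


def _write_bundle(report: PipelineReport, cfg: PipelineConfig, out: Path) -> None:
    from .io import write_table, write_templates

    write_table(report.metrics, out / "metrics.csv")
    write_table(report.covariates, out / "covariates.csv")
    if len(report.stat_table):
        write_table(report.stat_table, out / "group_comparison.csv")
    if len(report.correlations):
        write_table(report.correlations, out / "correlations.csv")
    if len(report.regression.table):
        write_table(report.regression.table, out / "regression.csv")
    write_table(report.classification.to_frame(), out / "classification.csv")
    if report.classification.roc_points is not None:
        write_table(pd.DataFrame(report.classification.roc_points,
                                 columns=["fpr", "tpr"]), out / "roc.csv")
    layout0 = None
    try:
        from .layout import make_layout as _ml
        layout0 = _ml(report.group_templates.n_channels)
    except Exception:
        pass
    if layout0 is not None:
        write_templates(report.group_templates, layout0, out / "templates.csv")

    provenance = {
        "mstates_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "config": cfg.to_dict(),
        "selected_ks": report.selected_ks,
        "sex_chi2": {"chi2": report.sex_chi2[0], "p": report.sex_chi2[1]},
        "cv_accuracy": report.cv_scores.tolist(),
        "test_accuracy": report.classification.accuracy,
        "auc": report.classification.auc,
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2))

    lines = ["mstates pipeline report", "=" * 40, ""]
    lines.append(f"subjects: {len(report.metrics)}; "
                 f"median selected k: {int(np.median(report.selected_ks))}")
    lines.append(f"sex chi2 = {report.sex_chi2[0]:.3f}, p = {report.sex_chi2[1]:.3f}")
    lines.append(f"CV accuracy: {report.cv_scores.mean():.3f} "
                 f"(folds: {np.round(report.cv_scores, 3).tolist()})")
    lines.append(f"test accuracy: {report.classification.accuracy:.3f}, "
                 f"AUC: {report.classification.auc:.3f}")
    (out / "report.txt").write_text("\n".join(lines) + "\n")
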