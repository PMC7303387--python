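"""Factorial pipeline orchestration: enumerate method combinations, run
every stage over a two-session dataset, and assemble the metric report.

A pipeline is one choice per stage -- motion correction x smoothing FWHM
x regression variant x thresholding method.  The full study menu
(4 x 5 x 5 x 4) yields 400 pipelines; with 8 activation maps, 10
subjects and 2 sessions that is 64,000 planned activation-map analyses.
Shared upstream stages (one motion-corrected run feeding every
smoothing/regression/threshold combination) are computed once by loop
nesting, and Monte-Carlo cluster-size tables are cached by rounded
smoothness, so the factorial costs far less than its face value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path

import numpy as np
import pandas as pd

from . import cluster_metrics as cm
from . import stats_compare as sc
from . import thresholding as th
from .core import Bold4D
from .glm import REGRESSION_VARIANTS, build_design, fit_ols, fit_reml_ar1
from .paradigm import build_paradigm
from .preprocess import (
    MOTION_METHODS,
    framewise_displacement,
    motion_correct_run,
    smooth_in_mask,
)
from .simulate import (
    RUN_IDS,
    SimulationConfig,
    SyntheticDataset,
    default_truths,
    simulate_dataset,
)

log = logging.getLogger(__name__)

SMOOTHING_FWHMS = (0, 3, 6, 9, 12)

#: the full study menu (the two unimplemented motion arms are pluggable)
FULL_MENU = {
    "motion": ("NoMoCo", "2D+3D", "Rigid3D", "Affine"),
    "smoothing": SMOOTHING_FWHMS,
    "regression": REGRESSION_VARIANTS,
    "threshold": th.THRESHOLD_METHODS,
}


@dataclass(frozen=True)
class PipelineSpec:
    """One processing combination; the label is the dot-joined 4-tuple."""

    motion: str
    smoothing: float
    regression: str
    threshold: str

    @property
    def label(self) -> str:
        return (f"{self.motion}.Blur{int(self.smoothing):02d}."
                f"{self.regression}.{self.threshold}")


@dataclass
class StudyConfig:
    """Everything needed to run a study sweep on a synthetic cohort."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    runs: tuple[str, ...] = RUN_IDS
    motion_methods: tuple[str, ...] = MOTION_METHODS
    smoothing_fwhms: tuple[float, ...] = SMOOTHING_FWHMS
    regression_variants: tuple[str, ...] = REGRESSION_VARIANTS
    threshold_methods: tuple[str, ...] = th.THRESHOLD_METHODS
    mc_iterations: int = 1000
    alpha: float = 0.05
    min_cluster_voxels: int = cm.MIN_CLUSTER_VOXELS
    roi_prevalence: float = cm.ROI_PREVALENCE
    match_max_dist_mm: float = cm.MATCH_MAX_DIST_MM


def enumerate_pipelines(config: StudyConfig) -> list[PipelineSpec]:
    """Cartesian product of the stage menus, in deterministic stage order."""
    if not all([config.motion_methods, config.smoothing_fwhms,
                config.regression_variants, config.threshold_methods]):
        raise ValueError("every stage needs at least one method")
    return [
        PipelineSpec(m, s, r, t)
        for m, s, r, t in product(
            config.motion_methods, config.smoothing_fwhms,
            config.regression_variants, config.threshold_methods,
        )
    ]


def activation_maps_for_runs(runs) -> list[tuple[str, str]]:
    """(run, condition) activation types; the five-run battery yields 8."""
    out = []
    for r in runs:
        for cond in build_paradigm(r).condition_labels:
            out.append((r, cond))
    return out


def planned_analyses(
    n_pipelines: int, n_activation_maps: int, n_subjects: int,
    n_sessions: int = 2,
) -> int:
    """Bookkeeping: total planned activation-map analyses."""
    return n_pipelines * n_activation_maps * n_subjects * n_sessions


@dataclass
class StudyReport:
    """Outputs of one study sweep."""

    records: pd.DataFrame                 # one row per matched cluster pair
    summaries: dict[tuple[str, str], sc.StageSummary]
    pipelines: list[PipelineSpec]
    errors: list[dict]
    n_planned: int
    n_completed: int

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.records.to_csv(out / "metric_records.tsv", sep="\t", index=False)
        frames = [sc.comparisons_frame(s) for s in self.summaries.values()]
        frames = [f for f in frames if not f.empty]
        if frames:
            pd.concat(frames, ignore_index=True).to_csv(
                out / "method_comparisons.tsv", sep="\t", index=False
            )
        summary_rows = [
            {"stage": stage, "metric": metric, "method": m,
             "percent_better": pct,
             "n_comparisons": summ.n_comparisons[m]}
            for (stage, metric), summ in self.summaries.items()
            for m, pct in summ.percent_better.items()
        ]
        pd.DataFrame(
            summary_rows,
            columns=["stage", "metric", "method", "percent_better",
                     "n_comparisons"],
        ).to_csv(out / "stage_summaries.tsv", sep="\t", index=False)
        if not self.records.empty:
            sc.long_format_metrics(self.records).to_csv(
                out / "metrics_long.tsv", sep="\t", index=False
            )
        pd.DataFrame(self.errors).to_csv(out / "errors.tsv", sep="\t",
                                         index=False)


def _threshold_one(stat, method, dataset, config, cluster_tables,
                   voxel_mm, mc_seed):
    """Apply one thresholding method, caching Clst null tables by smoothness."""
    if method == "Clst":
        smooth = th.estimate_smoothness(stat.residuals, stat.mask, voxel_mm)
        fwhm_key = round(smooth.geometric_mean * 2) / 2  # 0.5 mm bins
        if fwhm_key not in cluster_tables:
            cluster_tables[fwhm_key] = th.cluster_size_threshold(
                stat.mask, fwhm_key, voxel_mm,
                n_iter=config.mc_iterations, seed=mc_seed,
            )
        ctx = th.ThresholdContext(cluster_table=cluster_tables[fwhm_key])
    elif method == "AMPLE":
        ctx = th.ThresholdContext(atlas=dataset.atlas)
    else:
        ctx = th.ThresholdContext()
    return th.apply_threshold(stat, method, ctx)


def run_study(
    config: StudyConfig, dataset: SyntheticDataset | None = None
) -> StudyReport:
    """Run the full factorial sweep and compute test-retest metrics.

    Per-unit failures are logged into the report's error ledger and
    skipped, never aborting the sweep.  Fully reproducible from the
    simulation seed.
    """
    if dataset is None:
        truths = {r: default_truths(r) for r in config.runs}
        dataset = simulate_dataset(config.simulation, truths, runs=config.runs)
    pipelines = enumerate_pipelines(config)
    amaps = activation_maps_for_runs(config.runs)
    subjects = dataset.subjects
    n_planned = planned_analyses(len(pipelines), len(amaps), len(subjects))

    voxel_mm = float(np.abs(np.diag(dataset.affine)[:3]).mean())
    cluster_tables: dict[float, th.ClusterSizeTable] = {}
    errors: list[dict] = []
    active: dict[tuple, np.ndarray] = {}     # bool activation per analysis
    tmaps: dict[tuple, np.ndarray] = {}      # float32 t-map per GLM product
    n_completed = 0
    mc_seed = int(abs(dataset.config.seed)) % (2**31 - 1)
    needs_motion = any(v in config.regression_variants
                       for v in ("Cen2", "Cen5", "MPC"))

    for subject in subjects:
        for session in (1, 2):
            for run_id in config.runs:
                member = dataset.members[(subject, session, run_id)]
                paradigm = dataset.paradigms[run_id]
                corrected: dict[str, tuple] = {}
                # censoring/covariate variants always use the rigid estimate
                est_motion = None
                if needs_motion:
                    corrected["Rigid3D"] = motion_correct_run(
                        member.bold, "Rigid3D"
                    )
                    est_motion = corrected["Rigid3D"][1]
                fd = (framewise_displacement(est_motion)
                      if est_motion is not None else None)
                for mo in config.motion_methods:
                    if mo not in corrected:
                        corrected[mo] = motion_correct_run(member.bold, mo)
                    bold_mc = corrected[mo][0]
                    for fwhm in config.smoothing_fwhms:
                        data_sm = smooth_in_mask(
                            bold_mc.data, fwhm, bold_mc.mask, voxel_mm
                        )
                        bold_sm = Bold4D(
                            data=data_sm, affine=bold_mc.affine,
                            tr_seconds=bold_mc.tr_seconds, mask=bold_mc.mask,
                        )
                        for reg in config.regression_variants:
                            try:
                                design = build_design(
                                    paradigm, reg,
                                    motion=est_motion, fd=fd,
                                )
                                fitter = (fit_reml_ar1 if reg == "REML"
                                          else fit_ols)
                                stat_maps = fitter(bold_sm, design)
                            except Exception as exc:  # noqa: BLE001
                                errors.append({
                                    "subject": subject, "session": session,
                                    "run": run_id, "motion": mo,
                                    "smoothing": fwhm, "regression": reg,
                                    "stage": "glm", "error": str(exc),
                                })
                                log.warning("glm failed: %s", exc)
                                continue
                            for cond, stat in stat_maps.items():
                                tmaps[(mo, fwhm, reg, subject, session,
                                       run_id, cond)] = \
                                    stat.tmap.astype(np.float32)
                            for thr in config.threshold_methods:
                                for cond, stat in stat_maps.items():
                                    try:
                                        amap = _threshold_one(
                                            stat, thr, dataset, config,
                                            cluster_tables, voxel_mm, mc_seed,
                                        )
                                    except Exception as exc:  # noqa: BLE001
                                        errors.append({
                                            "subject": subject,
                                            "session": session,
                                            "run": run_id, "motion": mo,
                                            "smoothing": fwhm,
                                            "regression": reg,
                                            "threshold": thr,
                                            "stage": "threshold",
                                            "error": str(exc),
                                        })
                                        continue
                                    spec = PipelineSpec(mo, fwhm, reg, thr)
                                    active[(spec.label, subject, session,
                                            run_id, cond)] = amap.active
                                    n_completed += 1

    # ROI masks per activation type, across pipelines x subjects x sessions
    rois = {}
    for run_id, cond in amaps:
        maps = [v for k, v in active.items() if k[3] == run_id and k[4] == cond]
        if maps:
            rois[(run_id, cond)] = cm.build_roi_mask(
                maps, prevalence=config.roi_prevalence
            )

    # cluster extraction, ROI filtering, cross-session matching, metrics
    rows = []
    for spec in pipelines:
        for subject in subjects:
            for run_id, cond in amaps:
                roi = rois.get((run_id, cond))
                if roi is None:
                    continue
                session_clusters = {}
                ok = True
                for session in (1, 2):
                    akey = (spec.label, subject, session, run_id, cond)
                    tkey = (spec.motion, spec.smoothing, spec.regression,
                            subject, session, run_id, cond)
                    if akey not in active or tkey not in tmaps:
                        ok = False
                        break
                    amap_obj = th.ActivationMap(
                        active=active[akey],
                        tmap=tmaps[tkey].astype(float),
                        method=spec.threshold,
                    )
                    clusters = cm.find_clusters(
                        amap_obj, dataset.affine,
                        min_voxels=config.min_cluster_voxels,
                    )
                    session_clusters[session] = cm.filter_by_roi(
                        clusters, roi, dataset.affine
                    )
                if not ok:
                    continue
                pairs = cm.match_clusters(
                    session_clusters[1], session_clusters[2],
                    max_dist_mm=config.match_max_dist_mm,
                )
                for pair in pairs:
                    rows.append(cm.metric_record(pair, tags={
                        "motion": spec.motion,
                        "smoothing": spec.smoothing,
                        "regression": spec.regression,
                        "threshold": spec.threshold,
                        "subject": subject,
                        "run": run_id,
                        "condition": cond,
                        "activation_map": f"{run_id}:{cond}",
                    }))

    records_df = pd.DataFrame(rows)
    summaries = {}
    if not records_df.empty:
        for stage in sc.STAGES:
            if records_df[stage].astype(str).nunique() < 2:
                continue
            for metric in sc.METRICS:
                summaries[(stage, metric)] = sc.summarize_stage(
                    records_df, stage, metric, alpha=config.alpha
                )
    return StudyReport(records=records_df, summaries=summaries,
                       pipelines=pipelines, errors=errors,
                       n_planned=n_planned, n_completed=n_completed)
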