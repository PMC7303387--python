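"""Statistical comparison of test-retest metrics across processing methods.

For each processing stage (motion correction, smoothing, regression,
thresholding) and each activation map, metric values are pooled across
subjects and all combinations of the other stages, and every pair of the
stage's methods is compared with an unpaired pooled-variance t test,
Bonferroni-corrected across the number of pairwise comparisons times the
number of activation maps.  Effect sizes use Cohen's d with pooled
standard deviation over an n1 + n2 denominator (the study's convention;
the textbook n1 + n2 - 2 is available by keyword).  A stage summary
reports, per method, the percentage of its comparisons in which it was
significantly better (lower PDAV or DCM, higher DSC).

Kruskal-Wallis tests check whether the metric distributions differ at
all across a stage's methods before pairwise testing.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

STAGES = ("motion", "smoothing", "regression", "threshold")
METRICS = ("pdav_percent", "dcm_mm", "dsc")

#: direction in which each metric improves
HIGHER_IS_BETTER = {"pdav_percent": False, "dcm_mm": False, "dsc": True}


@dataclass
class MethodComparison:
    stage: str
    method_a: str
    method_b: str
    activation_map: str
    metric: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    t: float
    p_raw: float
    p_corrected: float
    d: float
    better: str | None


@dataclass
class StageSummary:
    stage: str
    metric: str
    percent_better: dict[str, float]
    n_comparisons: dict[str, int]
    comparisons: list[MethodComparison]


def kruskal_wallis(groups: list[np.ndarray]) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) and its chi-square p-value.

    If every value in every group is identical the test is undefined;
    (H, p) = (0, 1) by convention.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size == 0 for g in groups):
        raise ValueError("need at least two nonempty groups")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = sps.kruskal(*groups)
    return float(h), float(p)


def unpaired_ttest(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sample pooled-variance Student's t and two-sided p.

    Zero pooled variance with equal means yields (0, 1).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0 and a.mean() == b.mean():
        return 0.0, 1.0
    t, p = sps.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


def correct_multiplicity(
    p_raw, n_method_comparisons: int, n_activation_maps: int
):
    """Bonferroni correction across method pairs x activation maps."""
    if n_method_comparisons < 1 or n_activation_maps < 1:
        raise ValueError("comparison counts must be >= 1")
    p = np.asarray(p_raw, dtype=float)
    out = np.minimum(1.0, p * n_method_comparisons * n_activation_maps)
    return float(out) if out.ndim == 0 else out


def cohens_d(a: np.ndarray, b: np.ndarray,
             denominator: str = "n1+n2") -> float:
    """Cohen's d: mean difference over the pooled standard deviation.

    ``denominator`` selects the pooled-variance divisor: the study
    convention ``"n1+n2"`` (default) or the textbook ``"n1+n2-2"``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = a.size, b.size
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 values")
    div = {"n1+n2": n1 + n2, "n1+n2-2": n1 + n2 - 2}[denominator]
    s2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / div
    if s2 <= 0:
        raise ValueError("zero pooled standard deviation")
    return float((a.mean() - b.mean()) / np.sqrt(s2))


def _stage_methods(records: pd.DataFrame, stage: str) -> list[str]:
    return sorted(records[stage].astype(str).unique())


def stage_kruskal(records: pd.DataFrame, stage: str, metric: str,
                  activation_map: str | None = None) -> tuple[float, float]:
    """Kruskal-Wallis across a stage's methods, optionally per map."""
    df = records
    if activation_map is not None:
        df = df[df["activation_map"] == activation_map]
    groups = [df.loc[df[stage].astype(str) == m, metric].to_numpy()
              for m in _stage_methods(df, stage)]
    return kruskal_wallis(groups)


def summarize_stage(
    records: pd.DataFrame,
    stage: str,
    metric: str,
    alpha: float = 0.05,
    d_denominator: str = "n1+n2",
) -> StageSummary:
    """All pairwise method comparisons of one stage, plus percent-better.

    `records` is the tidy matched-pair table with one row per matched
    cluster pair, columns including the four stage tags, an
    ``activation_map`` tag, and the metric columns.  For each activation
    map and unordered method pair, values are pooled across subjects and
    the other three stages.  A method is significantly better when the
    corrected p is below `alpha` and its mean lies on the favorable
    side.  Percent-better for a method is over all comparisons that
    method appears in; methods with no data still appear with zero
    comparisons.
    """
    if stage not in STAGES:
        raise ValueError(f"unknown stage: {stage!r}")
    methods = _stage_methods(records, stage)
    if len(methods) < 2:
        raise ValueError("need records from at least two methods of the stage")
    maps = sorted(records["activation_map"].astype(str).unique())
    n_pairs = len(methods) * (len(methods) - 1) // 2
    higher_better = HIGHER_IS_BETTER[metric]

    comparisons: list[MethodComparison] = []
    better_count = {m: 0 for m in methods}
    total_count = {m: 0 for m in methods}
    for amap in maps:
        sub = records[records["activation_map"].astype(str) == amap]
        for ma, mb in combinations(methods, 2):
            va = sub.loc[sub[stage].astype(str) == ma, metric].to_numpy()
            vb = sub.loc[sub[stage].astype(str) == mb, metric].to_numpy()
            if va.size < 2 or vb.size < 2:
                continue
            t, p_raw = unpaired_ttest(va, vb)
            p_corr = correct_multiplicity(p_raw, n_pairs, len(maps))
            d = cohens_d(va, vb, denominator=d_denominator) \
                if (va.var(ddof=1) + vb.var(ddof=1)) > 0 else 0.0
            better = None
            if p_corr < alpha and va.mean() != vb.mean():
                a_better = (va.mean() > vb.mean()) == higher_better
                better = ma if a_better else mb
            comparisons.append(MethodComparison(
                stage=stage, method_a=ma, method_b=mb, activation_map=amap,
                metric=metric, n_a=va.size, n_b=vb.size,
                mean_a=float(va.mean()), mean_b=float(vb.mean()),
                t=t, p_raw=p_raw, p_corrected=p_corr, d=d, better=better,
            ))
            total_count[ma] += 1
            total_count[mb] += 1
            if better is not None:
                better_count[better] += 1

    percent = {
        m: (100.0 * better_count[m] / total_count[m]) if total_count[m] else 0.0
        for m in methods
    }
    return StageSummary(stage=stage, metric=metric, percent_better=percent,
                        n_comparisons=total_count, comparisons=comparisons)


def comparisons_frame(summary: StageSummary) -> pd.DataFrame:
    """Comparisons of a StageSummary as a tidy DataFrame."""
    return pd.DataFrame([vars(c) for c in summary.comparisons])


def long_format_metrics(records: pd.DataFrame) -> pd.DataFrame:
    """Box-plot-ready long table: one row per (pair, stage, metric)."""
    rows = []
    for stage in STAGES:
        melted = records.melt(
            id_vars=[stage, "activation_map"],
            value_vars=list(METRICS),
            var_name="metric", value_name="value",
        ).rename(columns={stage: "method"})
        melted["stage"] = stage
        rows.append(melted)
    return pd.concat(rows, ignore_index=True)
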