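"""Binary activation maps from t-statistic maps, four ways.

``Bon``   Bonferroni familywise correction, corrected p < .01.
``FDR``   Benjamini-Hochberg step-up, adjusted q < 1e-5.
``Clst``  voxelwise p < .0001 plus a Monte-Carlo-calibrated minimum
          cluster extent at corrected alpha .01.
``AMPLE`` t-statistics expressed as a percentage of the regional
          maximum over five brain sectors, thresholded at > 60%.

All tests are one-sided in the positive-t direction (task-positive
activation).  The cluster-extent null simulation and the data clustering
share 6-face connectivity so the null and the data are treated alike.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.stats import norm, t as t_dist
from statsmodels.stats.multitest import multipletests

from .glm import StatMap
from .simulate import REGION_LABELS

THRESHOLD_METHODS = ("Bon", "FDR", "Clst", "AMPLE")

BONFERRONI_ALPHA = 0.01
FDR_Q = 1e-5
CLUSTER_VOXEL_P = 1e-4
CLUSTER_ALPHA = 0.01
AMPLE_CUTOFF = 60.0

SIX_CONNECTIVITY = ndimage.generate_binary_structure(3, 1)


@dataclass
class SmoothnessEstimate:
    """Spatial FWHM of the noise field, per axis and as a geometric mean."""

    fwhm_mm: np.ndarray          # per-axis, length 3

    @property
    def geometric_mean(self) -> float:
        f = np.asarray(self.fwhm_mm, dtype=float)
        return float(np.exp(np.log(np.maximum(f, 1e-12)).mean())) if f.all() else 0.0


@dataclass
class ClusterSizeTable:
    """Minimum cluster extent (voxels) per corrected alpha, from Monte Carlo."""

    k_by_alpha: dict[float, int]
    voxel_p: float
    n_iterations: int
    seed: int

    def k(self, alpha: float) -> int:
        return self.k_by_alpha[alpha]


@dataclass
class ActivationMap:
    """Binary activation field plus provenance."""

    active: np.ndarray           # bool 3D
    tmap: np.ndarray
    method: str
    params: dict = field(default_factory=dict)


def p_from_t(t, dof: int):
    """One-sided (upper-tail) p-value under Student's t."""
    if dof < 1:
        raise ValueError("dof must be >= 1")
    return t_dist.sf(t, dof)


def bonferroni_threshold(stat: StatMap, alpha: float = BONFERRONI_ALPHA) -> ActivationMap:
    """Voxel active iff p multiplied by the in-mask voxel count is < alpha."""
    n = int(stat.mask.sum())
    if n == 0:
        raise ValueError("empty mask")
    p = p_from_t(stat.tmap[stat.mask], stat.dof)
    active = np.zeros(stat.mask.shape, dtype=bool)
    active[stat.mask] = p * n < alpha
    return ActivationMap(active=active, tmap=stat.tmap, method="Bon",
                         params={"alpha": alpha, "n_voxels": n})


def fdr_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def fdr_threshold(stat: StatMap, q: float = FDR_Q) -> ActivationMap:
    """Voxel active iff its BH-adjusted p is strictly below q."""
    p = p_from_t(stat.tmap[stat.mask], stat.dof)
    adj = fdr_adjust(p)
    active = np.zeros(stat.mask.shape, dtype=bool)
    active[stat.mask] = adj < q
    return ActivationMap(active=active, tmap=stat.tmap, method="FDR",
                         params={"q": q})


def estimate_smoothness(
    residuals: np.ndarray, mask: np.ndarray, voxel_size_mm: float
) -> SmoothnessEstimate:
    """Per-axis spatial FWHM of the residual noise field.

    Gaussian-field estimator: residuals are variance-normalized per
    voxel, then for each axis the lag-1 spatial autocorrelation
    rho = 1 - var(diff) / (2 var) is pooled over volumes and converted
    to the FWHM of the Gaussian kernel that would produce it on white
    noise (ACF exp(-d^2 / 4 sigma_k^2)).
    """
    if residuals.ndim != 4:
        raise ValueError("residuals must be 4D")
    if residuals.shape[3] < 10:
        raise ValueError("need at least 10 residual volumes")
    sd = residuals.std(axis=3)
    ok = mask & (sd > 0)
    norm_res = np.zeros_like(residuals)
    norm_res[ok] = residuals[ok] / sd[ok][:, None]

    fwhm = np.zeros(3)
    factor = 2.0 * np.sqrt(2.0 * np.log(2.0))
    for ax in range(3):
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[ax] = slice(None, -1)
        sl_hi[ax] = slice(1, None)
        pair = ok[tuple(sl_lo)] & ok[tuple(sl_hi)]
        if pair.sum() < 2:
            raise ValueError(f"fewer than 2 in-mask voxel pairs along axis {ax}")
        d = norm_res[tuple(sl_hi)][pair] - norm_res[tuple(sl_lo)][pair]
        v = 0.5 * (norm_res[tuple(sl_hi)][pair] ** 2
                   + norm_res[tuple(sl_lo)][pair] ** 2)
        rho = 1.0 - d.var() / (2.0 * v.mean())
        if rho <= 0:
            continue  # rougher than white noise: FWHM 0
        sigma_k2 = -voxel_size_mm ** 2 / (4.0 * np.log(rho))
        fwhm[ax] = factor * np.sqrt(sigma_k2)
    return SmoothnessEstimate(fwhm_mm=fwhm)


def cluster_size_threshold(
    mask: np.ndarray,
    smoothness: SmoothnessEstimate | float,
    voxel_size_mm: float,
    voxel_p: float = CLUSTER_VOXEL_P,
    alphas: tuple[float, ...] = (CLUSTER_ALPHA,),
    n_iter: int = 1000,
    seed: int = 0,
) -> ClusterSizeTable:
    """Monte-Carlo minimum cluster size for each corrected alpha.

    Each iteration draws a Gaussian random field with the given
    (isotropic, geometric-mean) smoothness inside the mask, thresholds
    at the one-sided `voxel_p`, and records the largest 6-connected
    cluster.  k(alpha) is the smallest size whose exceedance frequency
    over iterations is <= alpha.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if not mask.any():
        raise ValueError("degenerate mask")
    fwhm = (smoothness.geometric_mean
            if isinstance(smoothness, SmoothnessEstimate) else float(smoothness))
    sigma_vox = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / voxel_size_mm
    zthr = norm.isf(voxel_p)
    rng = np.random.default_rng(seed)
    max_sizes = np.zeros(n_iter, dtype=int)
    for i in range(n_iter):
        field3d = rng.standard_normal(mask.shape)
        if sigma_vox > 0:
            field3d = ndimage.gaussian_filter(field3d, sigma_vox)
        vals = field3d[mask]
        field3d = (field3d - vals.mean()) / vals.std()
        supra = (field3d > zthr) & mask
        if supra.any():
            lab, nlab = ndimage.label(supra, structure=SIX_CONNECTIVITY)
            max_sizes[i] = np.bincount(lab.ravel())[1:].max()
    k_by_alpha = {}
    for alpha in alphas:
        k = 1
        while (max_sizes >= k).mean() > alpha:
            k += 1
        k_by_alpha[alpha] = k
    return ClusterSizeTable(k_by_alpha=k_by_alpha, voxel_p=voxel_p,
                            n_iterations=n_iter, seed=seed)


def cluster_threshold(
    stat: StatMap,
    table: ClusterSizeTable,
    alpha: float = CLUSTER_ALPHA,
) -> ActivationMap:
    """Voxelwise p < voxel_p, then drop clusters smaller than k(alpha)."""
    p = p_from_t(stat.tmap[stat.mask], stat.dof)
    supra = np.zeros(stat.mask.shape, dtype=bool)
    supra[stat.mask] = p < table.voxel_p
    k_min = table.k(alpha)
    lab, nlab = ndimage.label(supra, structure=SIX_CONNECTIVITY)
    if nlab:
        sizes = np.bincount(lab.ravel())
        keep = sizes >= k_min
        keep[0] = False
        supra = keep[lab]
    return ActivationMap(active=supra, tmap=stat.tmap, method="Clst",
                         params={"voxel_p": table.voxel_p, "alpha": alpha,
                                 "k_min": k_min})


def ample_map(stat: StatMap, atlas: np.ndarray) -> np.ndarray:
    """t-statistics as a percentage of each region's maximum t.

    The atlas labels every mask voxel with one of five sectors
    (frontal, occipital, parietal, temporal, other).  A region whose
    maximum t is nonpositive yields no values (flagged with a warning).
    """
    out = np.zeros(stat.tmap.shape)
    for code in range(1, len(REGION_LABELS) + 1):
        region = (atlas == code) & stat.mask
        if not region.any():
            continue
        tmax = stat.tmap[region].max()
        if tmax <= 0:
            warnings.warn(
                f"region {REGION_LABELS[code - 1]!r} has nonpositive max t; "
                "no AMPLE values produced there",
                RuntimeWarning,
            )
            continue
        out[region] = 100.0 * stat.tmap[region] / tmax
    return out


def ample_threshold(stat: StatMap, atlas: np.ndarray,
                    cutoff: float = AMPLE_CUTOFF) -> ActivationMap:
    """Voxel active iff its AMPLE value strictly exceeds the cutoff."""
    vals = ample_map(stat, atlas)
    active = (vals > cutoff) & stat.mask
    return ActivationMap(active=active, tmap=stat.tmap, method="AMPLE",
                         params={"cutoff": cutoff})


@dataclass
class ThresholdContext:
    """Side information for methods that need it (atlas, null calibration)."""

    atlas: np.ndarray | None = None
    cluster_table: ClusterSizeTable | None = None
    smoothness: SmoothnessEstimate | None = None
    voxel_size_mm: float | None = None
    n_iter: int = 1000
    seed: int = 0


def apply_threshold(
    stat: StatMap, method: str, context: ThresholdContext | None = None
) -> ActivationMap:
    """Dispatch a StatMap to one of the four thresholding methods."""
    context = context or ThresholdContext()
    if method == "Bon":
        return bonferroni_threshold(stat)
    if method == "FDR":
        return fdr_threshold(stat)
    if method == "AMPLE":
        if context.atlas is None:
            raise ValueError("AMPLE requires a region atlas in the context")
        return ample_threshold(stat, context.atlas)
    if method == "Clst":
        table = context.cluster_table
        if table is None:
            if context.smoothness is None or context.voxel_size_mm is None:
                raise ValueError(
                    "Clst requires a cluster table or smoothness + voxel size"
                )
            table = cluster_size_threshold(
                stat.mask, context.smoothness, context.voxel_size_mm,
                n_iter=context.n_iter, seed=context.seed,
            )
        return cluster_threshold(stat, table)
    raise ValueError(f"unknown thresholding method: {method!r}")
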