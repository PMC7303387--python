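"""Cluster extraction, ROI prevalence masks, cross-session matching, and
the three test-retest metrics.

Clusters are 6-connected supra-threshold components of at least 12
voxels (768 ul at 4 mm isotropic), each carrying a t-weighted center of
mass in mm.  A cluster enters the analysis only if its center of mass
falls inside an ROI mask built from the prevalence of activation across
analyses (voxels active in at least 10% of maps).  Test-session clusters
are matched to the closest retest cluster with a center-of-mass distance
of at most 10 mm; a retest cluster may be matched more than once.

Metrics per matched pair:

    PDAV = |V1 - V2| / ((V1 + V2) / 2) * 100      (%; ideal 0)
    DCM  = ||com1 - com2||                        (mm; ideal 0)
    DSC  = 2 |C1 n C2| / (|C1| + |C2|)            (ideal 1)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import mm_to_voxel, voxel_to_mm
from .thresholding import SIX_CONNECTIVITY, ActivationMap

MIN_CLUSTER_VOXELS = 12
ROI_PREVALENCE = 0.10
MATCH_MAX_DIST_MM = 10.0


@dataclass
class Cluster:
    """A connected supra-threshold voxel set with its t statistics."""

    voxels: np.ndarray       # (n, 3) int indices
    t_values: np.ndarray     # (n,)
    volume_ul: float
    com_mm: np.ndarray       # t-weighted center of mass, mm
    tags: dict = field(default_factory=dict)

    @property
    def n_voxels(self) -> int:
        return self.voxels.shape[0]

    def voxel_set(self) -> set[tuple[int, int, int]]:
        return {tuple(v) for v in self.voxels}


@dataclass
class RoiMask:
    """Prevalence-based region-of-interest mask for one activation type."""

    mask: np.ndarray
    prevalence: float
    n_maps: int


@dataclass
class ClusterPair:
    """A test cluster matched to its closest retest cluster (<= 10 mm)."""

    test: Cluster
    retest: Cluster
    dcm_mm: float


def weighted_com(voxels: np.ndarray, t_values: np.ndarray,
                 affine: np.ndarray) -> np.ndarray:
    """t-weighted center of mass in mm: sum(t x) / sum(t) per axis."""
    t = np.asarray(t_values, dtype=float)
    total = t.sum()
    if total <= 0:
        raise ValueError("weighted center of mass requires positive total weight")
    com_vox = (voxels * t[:, None]).sum(axis=0) / total
    return voxel_to_mm(affine, com_vox)


def find_clusters(
    act: ActivationMap,
    affine: np.ndarray,
    min_voxels: int = MIN_CLUSTER_VOXELS,
    tags: dict | None = None,
) -> list[Cluster]:
    """6-connected components of an activation map, small ones discarded."""
    voxel_vol_ul = float(abs(np.linalg.det(affine[:3, :3])))
    lab, nlab = ndimage.label(act.active, structure=SIX_CONNECTIVITY)
    clusters = []
    for i in range(1, nlab + 1):
        idx = np.argwhere(lab == i)
        if idx.shape[0] < min_voxels:
            continue
        tv = act.tmap[tuple(idx.T)]
        clusters.append(
            Cluster(
                voxels=idx,
                t_values=tv,
                volume_ul=idx.shape[0] * voxel_vol_ul,
                com_mm=weighted_com(idx, tv, affine),
                tags=dict(tags or {}),
            )
        )
    return clusters


def build_roi_mask(binary_maps: list[np.ndarray],
                   prevalence: float = ROI_PREVALENCE) -> RoiMask:
    """Voxels active in at least `prevalence` of the maps (inclusive)."""
    if not binary_maps:
        raise ValueError("need at least one activation map")
    stack = np.stack([m.astype(bool) for m in binary_maps])
    frac = stack.mean(axis=0)
    inc = (frac >= prevalence) & (stack.any(axis=0))
    return RoiMask(mask=inc, prevalence=prevalence, n_maps=len(binary_maps))


def filter_by_roi(clusters: list[Cluster], roi: RoiMask,
                  affine: np.ndarray) -> list[Cluster]:
    """Keep clusters whose center of mass lies in an ROI voxel.

    The mm center of mass is mapped to its containing voxel by flooring
    the fractional voxel coordinate.
    """
    kept = []
    shape = roi.mask.shape
    for c in clusters:
        vox = np.floor(mm_to_voxel(affine, c.com_mm)).astype(int)
        if np.any(vox < 0) or np.any(vox >= shape):
            continue
        if roi.mask[tuple(vox)]:
            kept.append(c)
    return kept


def dcm(com1: np.ndarray, com2: np.ndarray) -> float:
    """Euclidean distance between two centers of mass (mm)."""
    return float(np.linalg.norm(np.asarray(com1, float) - np.asarray(com2, float)))


def match_clusters(
    test: list[Cluster],
    retest: list[Cluster],
    max_dist_mm: float = MATCH_MAX_DIST_MM,
) -> list[ClusterPair]:
    """For each test cluster, the closest retest cluster within 10 mm.

    Matching is independent per test cluster, so a retest cluster may be
    matched to more than one test cluster.  The distance bound is
    inclusive.
    """
    pairs = []
    for tc in test:
        best = None
        best_d = None
        for rc in retest:
            d = dcm(tc.com_mm, rc.com_mm)
            if d <= max_dist_mm and (best_d is None or d < best_d):
                best, best_d = rc, d
        if best is not None:
            pairs.append(ClusterPair(test=tc, retest=best, dcm_mm=best_d))
    return pairs


def pdav(v1: float, v2: float) -> float:
    """Percent difference in activation volume; range [0, 200]."""
    if v1 + v2 <= 0:
        raise ValueError("at least one volume must be positive")
    return abs(v1 - v2) / ((v1 + v2) / 2.0) * 100.0


def dsc(c1, c2) -> float:
    """Dice similarity coefficient of two voxel sets."""
    s1 = c1 if isinstance(c1, set) else {tuple(v) for v in np.asarray(c1)}
    s2 = c2 if isinstance(c2, set) else {tuple(v) for v in np.asarray(c2)}
    if not s1 and not s2:
        raise ValueError("both voxel sets are empty")
    return 2.0 * len(s1 & s2) / (len(s1) + len(s2))


def metric_record(pair: ClusterPair, tags: dict | None = None) -> dict:
    """PDAV / DCM / DSC of one matched pair, plus its pipeline tags."""
    rec = {
        "pdav_percent": pdav(pair.test.volume_ul, pair.retest.volume_ul),
        "dcm_mm": pair.dcm_mm,
        "dsc": dsc(pair.test.voxel_set(), pair.retest.voxel_set()),
    }
    rec.update(pair.test.tags)
    rec.update(tags or {})
    return rec
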