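"""Synthetic two-session block-design BOLD datasets with known ground truth.

The generator emulates the structure of a two-session, multi-subject
test-retest study: each subject is scanned in two sessions, each session
comprising up to five block-design runs on a shared 4 mm isotropic grid.
Activation is injected as spherical clusters (hard sphere with a
raised-cosine roll-off of one voxel at the edge) whose time course is
``amplitude x condition_regressor``; with a baseline of 100, amplitude is
read directly in percent signal change at the response peak.

Noise is built white -> spatially smoothed -> AR(1) filtered in time ->
scaled to ``noise_sd``, so each voxel's series has a known lag-1
autocorrelation and the field a known spatial smoothness.  Between-session
variability jitters cluster centers and amplitudes in session 2; optional
rigid head motion is applied per volume by resampling.  Everything is
reproducible from the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage, signal

from .core import Bold4D, centered_affine, mm_to_voxel
from .paradigm import RUN_IDS, TaskParadigm, build_paradigm, condition_regressor
from .preprocess import apply_rigid

REGION_LABELS = ("frontal", "occipital", "parietal", "temporal", "other")


@dataclass(frozen=True)
class GroundTruthCluster:
    """A spherical activation source tied to one task condition."""

    center_mm: tuple[float, float, float]
    radius_mm: float
    amplitude: float          # percent signal change at response peak
    condition_label: str

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError("radius_mm must be positive")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults emulate a realistic single-subject task fMRI regime on a
    desk-scale grid: temporal SNR 100 (baseline 100, noise_sd 1), lag-1
    autocorrelation 0.3, noise smoothness 6 mm, 2 mm between-session
    center jitter and 10% amplitude jitter.
    """

    n_subjects: int = 10
    grid_shape: tuple[int, int, int] = (32, 32, 24)
    voxel_size_mm: float = 4.0
    baseline: float = 100.0
    noise_sd: float = 1.0
    ar1_rho: float = 0.3
    noise_fwhm_mm: float = 6.0
    session_com_jitter_sd_mm: float = 2.0
    session_amplitude_jitter_sd: float = 0.10
    motion_profile: np.ndarray | str = "none"
    identical_sessions: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.noise_sd, self.noise_fwhm_mm,
               self.session_com_jitter_sd_mm,
               self.session_amplitude_jitter_sd) < 0:
            raise ValueError("standard deviations must be nonnegative")
        if not (0 <= self.ar1_rho < 1):
            raise ValueError("ar1_rho must lie in [0, 1)")

    @property
    def affine(self) -> np.ndarray:
        return centered_affine(self.grid_shape, self.voxel_size_mm)


@dataclass
class SessionRun:
    """One generated (subject, session, run) member."""

    bold: Bold4D
    motion_true: np.ndarray                  # (n_volumes, 6)
    truths: tuple[GroundTruthCluster, ...]   # post-jitter


@dataclass
class SyntheticDataset:
    """All generated runs plus the shared geometry."""

    config: SimulationConfig
    members: dict[tuple[int, int, str], SessionRun]
    mask: np.ndarray
    affine: np.ndarray
    atlas: np.ndarray        # region codes, 0 = outside mask
    paradigms: dict[str, TaskParadigm]

    @property
    def subjects(self) -> list[int]:
        return sorted({k[0] for k in self.members})

    @property
    def runs(self) -> list[str]:
        return sorted({k[2] for k in self.members})


def make_brain_mask(grid_shape, voxel_size_mm: float) -> np.ndarray:
    """Analytic ellipsoid brain mask with semi-axes at 45% of each extent."""
    shape = np.asarray(grid_shape)
    axes = 0.45 * (shape - 1)
    coords = np.indices(grid_shape).astype(float)
    center = (shape - 1) / 2.0
    r2 = sum(((coords[i] - center[i]) / axes[i]) ** 2 for i in range(3))
    return r2 <= 1.0


def make_region_atlas(mask: np.ndarray, affine: np.ndarray) -> np.ndarray:
    """Partition the mask into five sectors standing in for cortical lobes.

    A central core is labelled "other"; the remainder is split by x/y
    quadrant into frontal (anterior-right), parietal (anterior-left),
    occipital (posterior-left) and temporal (posterior-right).  Codes are
    1-based indices into :data:`REGION_LABELS`; 0 marks out-of-mask.
    """
    shape = np.asarray(mask.shape)
    coords = np.indices(mask.shape).astype(float)
    mm = np.stack(
        [sum(affine[i, j] * coords[j] for j in range(3)) + affine[i, 3]
         for i in range(3)]
    )
    core_radius = 0.25 * float(np.min((shape - 1) * np.abs(np.diag(affine)[:3]))) / 2.0
    atlas = np.zeros(mask.shape, dtype=np.int8)
    r = np.sqrt((mm ** 2).sum(axis=0))
    quad = np.select(
        [
            (mm[0] >= 0) & (mm[1] >= 0),
            (mm[0] < 0) & (mm[1] >= 0),
            (mm[0] < 0) & (mm[1] < 0),
        ],
        [1, 3, 2],
        default=4,
    )
    atlas[mask] = quad[mask]
    atlas[mask & (r <= core_radius)] = 5
    return atlas


def default_truths(run_id: str) -> tuple[GroundTruthCluster, ...]:
    """One well-separated spherical truth per condition of a run.

    Centers sit in plausible sectors of the ellipsoid (language sources
    anterior, motor superior, visual posterior); radius 10 mm and 2%
    amplitude give clusters comfortably above the corrected thresholds
    at the default noise level.
    """
    locs = {
        "run1": {"word_repetition": (-20, 24, 4)},
        "run2": {"covert_verb": (-24, 20, 8)},
        "run3": {"overt_verb": (-20, 24, 0)},
        "run4": {"finger": (-16, -8, 20), "foot": (8, -4, 24),
                 "lips": (-28, 0, 12)},
        "run5": {"landmark": (12, -32, 0), "detection": (-12, -32, 4)},
    }
    if run_id not in locs:
        raise ValueError(f"unknown run_id: {run_id!r}")
    return tuple(
        GroundTruthCluster(center_mm=c, radius_mm=10.0, amplitude=2.0,
                           condition_label=cond)
        for cond, c in locs[run_id].items()
    )


def _sphere_profile(grid_shape, affine, center_mm, radius_mm, voxel_size_mm):
    """Hard sphere with a raised-cosine edge roll-off of one voxel width."""
    coords = np.indices(grid_shape).astype(float)
    mm = [sum(affine[i, j] * coords[j] for j in range(3)) + affine[i, 3]
          for i in range(3)]
    r = np.sqrt(sum((mm[i] - center_mm[i]) ** 2 for i in range(3)))
    w = voxel_size_mm
    inner = max(radius_mm - w, 0.0)
    profile = np.zeros(grid_shape)
    profile[r <= inner] = 1.0
    edge = (r > inner) & (r <= radius_mm)
    profile[edge] = 0.5 * (1.0 + np.cos(np.pi * (r[edge] - inner) / (radius_mm - inner)))
    return profile


def _fwhm_to_sigma_vox(fwhm_mm: float, voxel_size_mm: float) -> float:
    return fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / voxel_size_mm


def _structured_noise(rng, shape4d, config: SimulationConfig,
                      mask: np.ndarray) -> np.ndarray:
    """White noise -> spatial smooth -> AR(1) in time -> scale to noise_sd."""
    noise = rng.standard_normal(shape4d)
    sig = _fwhm_to_sigma_vox(config.noise_fwhm_mm, config.voxel_size_mm)
    if sig > 0:
        noise = ndimage.gaussian_filter(noise, sigma=(sig, sig, sig, 0.0))
    rho = config.ar1_rho
    if rho > 0:
        noise = signal.lfilter([1.0], [1.0, -rho], noise, axis=3)
    sd = noise[mask].std()
    if sd > 0:
        noise *= config.noise_sd / sd
    return noise


def _jitter_truths(rng, truths, config: SimulationConfig):
    out = []
    for tr in truths:
        dc = rng.normal(0.0, config.session_com_jitter_sd_mm, size=3)
        da = rng.normal(0.0, config.session_amplitude_jitter_sd)
        out.append(replace(
            tr,
            center_mm=tuple(np.asarray(tr.center_mm) + dc),
            amplitude=tr.amplitude * (1.0 + da),
        ))
    return tuple(out)


def _motion_schedule(config: SimulationConfig, n_volumes: int) -> np.ndarray:
    prof = config.motion_profile
    if isinstance(prof, str):
        if prof == "none":
            return np.zeros((n_volumes, 6))
        raise ValueError(f"unknown motion profile: {prof!r}")
    prof = np.asarray(prof, dtype=float)
    if prof.ndim != 2 or prof.shape[1] != 6:
        raise ValueError("motion_profile must have shape (n, 6)")
    sched = np.zeros((n_volumes, 6))
    n = min(n_volumes, prof.shape[0])
    sched[:n] = prof[:n]
    if n < n_volumes:
        sched[n:] = prof[-1]
    return sched


def _rng_for(config: SimulationConfig, subject: int, session: int,
             run_id: str) -> np.random.Generator:
    run_idx = RUN_IDS.index(run_id)
    ss = np.random.SeedSequence(
        entropy=config.seed, spawn_key=(subject, session, run_idx)
    )
    return np.random.default_rng(ss)


def simulate_session(
    config: SimulationConfig,
    subject: int,
    session: int,
    run_id: str,
    truths: tuple[GroundTruthCluster, ...],
    mask: np.ndarray | None = None,
) -> tuple[Bold4D, np.ndarray, tuple[GroundTruthCluster, ...]]:
    """Generate one (subject, session, run) BOLD series.

    Session 2 receives center and amplitude jitter relative to the
    nominal truths; session 1 uses them as given.  With
    ``identical_sessions`` set, session 2 reuses session 1's random
    stream and skips the jitter, making the two sessions bit-identical
    (the idealized perfectly reproducible scan-rescan).  Returns the
    run, the true per-volume motion schedule and the truths actually
    injected.
    """
    paradigm = build_paradigm(run_id)
    affine = config.affine
    if mask is None:
        mask = make_brain_mask(config.grid_shape, config.voxel_size_mm)
    rng_session = 1 if config.identical_sessions else session
    rng = _rng_for(config, subject, rng_session, run_id)

    jittered = truths
    if session == 2 and not config.identical_sessions and truths and (
        config.session_com_jitter_sd_mm > 0
        or config.session_amplitude_jitter_sd > 0
    ):
        jittered = _jitter_truths(rng, truths, config)
    for tr in jittered:
        vox = mm_to_voxel(affine, np.asarray(tr.center_mm))
        if np.any(vox < 0) or np.any(vox > np.asarray(config.grid_shape) - 1):
            raise ValueError(f"truth center {tr.center_mm} outside grid")

    n = paradigm.n_volumes
    clean = np.empty(config.grid_shape + (n,))
    clean[...] = config.baseline
    for tr in jittered:
        profile = _sphere_profile(
            config.grid_shape, affine, tr.center_mm, tr.radius_mm,
            config.voxel_size_mm,
        )
        course = tr.amplitude * condition_regressor(paradigm, tr.condition_label)
        clean += profile[..., None] * course[None, None, None, :]
    clean *= mask[..., None]

    motion = _motion_schedule(config, n)
    if np.any(motion):
        moved = np.empty_like(clean)
        for t in range(n):
            if np.any(motion[t]):
                moved[..., t] = apply_rigid(clean[..., t], motion[t], affine)
            else:
                moved[..., t] = clean[..., t]
        clean = moved

    data = clean
    if config.noise_sd > 0:
        data = clean + _structured_noise(rng, clean.shape, config, mask)

    bold = Bold4D(data=data, affine=affine, tr_seconds=paradigm.tr_seconds,
                  mask=mask)
    return bold, motion, jittered


def simulate_dataset(
    config: SimulationConfig,
    truths_per_run: dict[str, tuple[GroundTruthCluster, ...]] | None = None,
    runs: tuple[str, ...] = RUN_IDS,
) -> SyntheticDataset:
    """Generate the full cohort: n_subjects x 2 sessions x requested runs."""
    if truths_per_run is None:
        truths_per_run = {r: default_truths(r) for r in runs}
    mask = make_brain_mask(config.grid_shape, config.voxel_size_mm)
    affine = config.affine
    atlas = make_region_atlas(mask, affine)
    members: dict[tuple[int, int, str], SessionRun] = {}
    for subject in range(1, config.n_subjects + 1):
        for session in (1, 2):
            for run_id in runs:
                bold, motion, jittered = simulate_session(
                    config, subject, session, run_id,
                    truths_per_run.get(run_id, ()), mask=mask,
                )
                members[(subject, session, run_id)] = SessionRun(
                    bold=bold, motion_true=motion, truths=jittered
                )
    return SyntheticDataset(
        config=config, members=members, mask=mask, affine=affine,
        atlas=atlas, paradigms={r: build_paradigm(r) for r in runs},
    )
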