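"""Block-design task paradigms and hemodynamic regressors.

The study battery comprises five runs acquired twice (test and retest
session): overt word repetition (run1), covert verb generation (run2),
overt verb generation (run3), a finger/foot/lip motor task (run4) and a
visual landmark-identification / detection task (run5).  Runs 1 and 3 use
sparse sampling, which is modelled here simply as a block design with an
effective TR of 5 s; the other runs use TR = 2.5 s.

Each paradigm is an ordered sequence of (condition, duration-in-TRs)
blocks; rest carries the reserved label ``"rest"``.  Task regressors are
built by convolving the condition boxcar with a canonical double-gamma
hemodynamic response function and sampling at the TR.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gamma as _gamma_dist

REST = "rest"

RUN_IDS = ("run1", "run2", "run3", "run4", "run5")


@dataclass(frozen=True)
class TaskParadigm:
    """Ordered rest/task block structure of one run, in TR units."""

    run_id: str
    tr_seconds: float
    blocks: tuple[tuple[str, int], ...]
    condition_labels: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if any(d < 1 for _, d in self.blocks):
            raise ValueError("all block durations must be >= 1 TR")
        labels = tuple(
            dict.fromkeys(c for c, _ in self.blocks if c != REST)
        )
        object.__setattr__(self, "condition_labels", labels)

    @property
    def n_volumes(self) -> int:
        return sum(d for _, d in self.blocks)

    def boxcar(self, condition: str) -> np.ndarray:
        """0/1 indicator of `condition` per volume (length n_volumes)."""
        out = np.zeros(self.n_volumes)
        t = 0
        for label, dur in self.blocks:
            if label == condition:
                out[t : t + dur] = 1.0
            t += dur
        return out

    def onsets(self) -> list[tuple[float, float, str]]:
        """(onset_s, duration_s, condition) for every non-rest block."""
        rows = []
        t = 0
        for label, dur in self.blocks:
            if label != REST:
                rows.append((t * self.tr_seconds, dur * self.tr_seconds, label))
            t += dur
        return rows


def _cycles(pattern: list[tuple[str, int]], n: int) -> list[tuple[str, int]]:
    return pattern * n


def build_paradigm(run_id: str) -> TaskParadigm:
    """Return the block structure of one of the five study runs.

    Volume totals are 76, 173, 88, 184 and 238 for runs 1-5.  Runs 1 and
    3 are sparse-sampled (effective TR 5 s); the rest use TR 2.5 s.
    """
    if run_id == "run1":  # overt word repetition
        blocks = [(REST, 4)] + _cycles([("word_repetition", 6), (REST, 6)], 6)
        tr = 5.0
    elif run_id == "run2":  # covert verb generation
        blocks = [(REST, 5)] + _cycles([("covert_verb", 12), (REST, 12)], 7)
        tr = 2.5
    elif run_id == "run3":  # overt verb generation
        blocks = [(REST, 4)] + _cycles([("overt_verb", 6), (REST, 6)], 7)
        tr = 5.0
    elif run_id == "run4":  # finger / foot / lips motor
        blocks = [(REST, 4)] + _cycles(
            [("finger", 6), ("foot", 6), ("lips", 6)], 10
        )
        tr = 2.5
    elif run_id == "run5":  # visual landmark / detection
        blocks = [(REST, 10)] + _cycles(
            [("landmark", 6), (REST, 7), ("detection", 6), (REST, 7)], 8
        )
        blocks += [(REST, 20)]
        tr = 2.5
    else:
        raise ValueError(f"unknown run_id: {run_id!r}")
    return TaskParadigm(run_id=run_id, tr_seconds=tr, blocks=tuple(blocks))


def canonical_hrf(time_s: np.ndarray) -> np.ndarray:
    """Canonical double-gamma HRF sampled at `time_s`, peak-normalized to 1.

    Response gamma peaks near 5-6 s, undershoot near 16 s, with a 6:1
    peak-to-undershoot ratio; the impulse response is causal (0 at t=0).
    """
    t = np.asarray(time_s, dtype=float)
    if t.size and t.min() < 0:
        raise ValueError("negative times not allowed for a causal HRF")
    peak = _gamma_dist.pdf(t, a=6.0, scale=1.0)
    undershoot = _gamma_dist.pdf(t, a=16.0, scale=1.0)
    h = peak - undershoot / 6.0
    # normalize on a fine internal grid so the unit is peak amplitude
    ref = np.arange(0.0, 32.0, 0.01)
    hmax = (_gamma_dist.pdf(ref, a=6.0, scale=1.0)
            - _gamma_dist.pdf(ref, a=16.0, scale=1.0) / 6.0).max()
    return h / hmax


def condition_regressor(
    paradigm: TaskParadigm, condition: str, dt: float = 0.1
) -> np.ndarray:
    """HRF-convolved stimulus time series for one condition, length n_volumes.

    The condition boxcar is laid out on a fine grid (`dt` seconds),
    convolved with :func:`canonical_hrf`, and sampled at the paradigm TR.
    A condition absent from the paradigm yields the zero vector.
    """
    n = paradigm.n_volumes
    tr = paradigm.tr_seconds
    fine_n = int(round(n * tr / dt))
    stim = np.zeros(fine_n)
    t = 0
    for label, dur in paradigm.blocks:
        if label == condition:
            i0 = int(round(t * tr / dt))
            i1 = int(round((t + dur) * tr / dt))
            stim[i0:i1] = 1.0
        t += dur
    if not stim.any():
        return np.zeros(n)
    hrf = canonical_hrf(np.arange(0.0, 32.0 + dt, dt))
    conv = np.convolve(stim, hrf)[:fine_n]
    conv /= conv.max()  # unit peak: the GLM beta reads in signal units
    # sample at volume acquisition times 0, TR, 2 TR, ...
    idx = np.round(np.arange(n) * tr / dt).astype(int)
    idx = np.clip(idx, 0, fine_n - 1)
    return conv[idx]
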