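import numpy as np
import pytest

import boldrepro as br


@pytest.fixture(scope="session")
def noiseless_run1():
    """One noiseless run1 session with the default truths (shared, read-only)."""
    cfg = br.SimulationConfig(
        n_subjects=1, noise_sd=0.0, session_com_jitter_sd_mm=0.0,
        session_amplitude_jitter_sd=0.0, seed=11,
    )
    truths = br.default_truths("run1")
    bold, motion, jittered = br.simulate_session(cfg, 1, 1, "run1", truths)
    return cfg, bold, truths


@pytest.fixture(scope="session")
def smooth_phantom():
    """A spatially smooth multi-blob 3D phantom for registration tests.

    Several well-separated blobs make all six rigid parameters
    identifiable (a single compact blob confounds small rotations with
    translations).
    """
    from scipy.ndimage import gaussian_filter

    from boldrepro.simulate import _sphere_profile

    shape = (32, 32, 24)
    affine = br.centered_affine(shape, 4.0)
    mask = br.make_brain_mask(shape, 4.0)
    vol = np.zeros(shape)
    centers = [(-20, 24, 4), (24, -16, 8), (-16, -24, 20),
               (20, 20, 24), (0, -32, 0)]
    for i, c in enumerate(centers):
        vol += (50.0 + 20.0 * i) * _sphere_profile(shape, affine, c, 12.0, 4.0)
    vol = gaussian_filter(vol, 1.0)  # soft edges on a zero background
    return vol, affine, mask


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def toy_bold(data: np.ndarray, tr: float = 2.5) -> br.Bold4D:
    """Wrap a small (X,Y,Z,T) array as a fully in-mask Bold4D."""
    mask = np.ones(data.shape[:3], dtype=bool)
    affine = br.centered_affine(data.shape[:3], 4.0)
    return br.Bold4D(data=data.astype(float), affine=affine,
                     tr_seconds=tr, mask=mask)
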