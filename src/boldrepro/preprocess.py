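"""Motion correction, framewise displacement and masked smoothing.

Motion parameters follow the 6-vector convention
``(rot_x_deg, rot_y_deg, rot_z_deg, trans_x_mm, trans_y_mm, trans_z_mm)``:
rotations in degrees about the grid center, translations in mm, one row
per volume, with the reference volume at zero.  Rigid correction
registers every volume to the first volume of the run by least-squares
intensity matching; after either correction arm the initial volume is
removed from the run, mirroring the common practice of discarding the
registration base from analysis.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage
from scipy.optimize import minimize

from .core import Bold4D

MOTION_METHODS = ("NoMoCo", "Rigid3D")

#: radius (mm) of the sphere used to convert rotations to displacement
FD_ROTATION_RADIUS_MM = 50.0


def rotation_matrix(rx_deg: float, ry_deg: float, rz_deg: float) -> np.ndarray:
    """Rotation about x, then y, then z (right-handed, degrees)."""
    rx, ry, rz = np.deg2rad([rx_deg, ry_deg, rz_deg])
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rz @ Ry @ Rx


def apply_rigid(
    volume: np.ndarray,
    params: np.ndarray,
    affine: np.ndarray,
    order: int = 1,
    cval: float = 0.0,
) -> np.ndarray:
    """Move an image rigidly by `params` (trilinear resampling by default).

    The transform rotates about the mm center of the grid and then
    translates, i.e. a point x maps to R(x - c) + c + t.  The returned
    image is the input observed under that head motion.
    """
    p = np.asarray(params, dtype=float)
    R = rotation_matrix(*p[:3])
    t = p[3:6]
    L = affine[:3, :3]
    b = affine[:3, 3]
    shape = np.asarray(volume.shape, dtype=float)
    c = L @ ((shape - 1) / 2.0) + b
    # output voxel v -> input voxel: L^-1 (R^-1 (L v + b - c - t) + c - b)
    Linv = np.linalg.inv(L)
    Rinv = R.T
    matrix = Linv @ Rinv @ L
    offset = Linv @ (Rinv @ (b - c - t) + c - b)
    return ndimage.affine_transform(
        volume, matrix, offset=offset, order=order, mode="constant", cval=cval
    )


def _negate_params(q: np.ndarray) -> np.ndarray:
    # inverse of a small rigid motion; exact for pure translations and
    # single-axis rotations, first-order otherwise
    return -np.asarray(q, dtype=float)


def rigid_register(
    moving: np.ndarray,
    reference: np.ndarray,
    affine: np.ndarray,
    x0: np.ndarray | None = None,
    xtol: float = 1e-3,
    stride: int = 2,
) -> tuple[np.ndarray, np.ndarray]:
    """Estimate the rigid head motion that maps `reference` to `moving`.

    Minimizes the sum-of-squares intensity difference between the
    rigidly resampled moving image and the reference (Powell search over
    the six parameters, started from rest and optionally from a warm
    start).  The cost is evaluated on a `stride`-decimated voxel grid
    for speed; the corrected volume is resampled at full resolution.
    Returns ``(motion_params, corrected_volume)`` where applying the
    *inverse* of ``motion_params`` to `moving` yields `corrected_volume`.
    """
    ref = np.asarray(reference, dtype=float)
    L = affine[:3, :3]
    b = affine[:3, 3]
    shape = np.asarray(ref.shape, dtype=float)
    c = L @ ((shape - 1) / 2.0) + b
    Linv = np.linalg.inv(L)

    def make_cost(step: int):
        sl_ref = ref[(slice(None, None, step),) * 3]
        oshape = sl_ref.shape
        Sm = np.eye(3) * step

        def cost(q: np.ndarray) -> float:
            R = rotation_matrix(*q[:3])
            t = q[3:6]
            matrix = Linv @ R.T @ L @ Sm
            offset = Linv @ (R.T @ (b - c - t) + c - b)
            resampled = ndimage.affine_transform(
                moving, matrix, offset=offset, output_shape=oshape, order=1
            )
            return float(((resampled - sl_ref) ** 2).sum())

        return cost

    coarse = make_cost(stride)
    starts = [np.zeros(6)]
    if x0 is not None and np.abs(x0).max() > 0.05:
        starts.append(_negate_params(x0))
    best = None
    for s in starts:
        res = minimize(coarse, s, method="Powell",
                       options={"xtol": xtol, "ftol": 1e-4, "maxiter": 200})
        if best is None or res.fun < best.fun:
            best = res
    if not best.success:
        warnings.warn(
            "rigid_register did not fully converge; returning best-found "
            f"parameters (cost {best.fun:.3g})",
            RuntimeWarning,
        )
    if stride > 1:
        # polish at full resolution from the decimated-grid optimum
        best = minimize(make_cost(1), best.x, method="Powell",
                        options={"xtol": xtol, "ftol": 1e-4, "maxiter": 1})
    q = best.x  # correcting transform
    corrected = apply_rigid(moving, q, affine)
    return _negate_params(q), corrected


def motion_correct_run(
    run: Bold4D, method: str = "Rigid3D"
) -> tuple[Bold4D, np.ndarray]:
    """Motion-correct a run and drop its initial (reference) volume.

    ``NoMoCo`` passes the data through with all-zero parameters;
    ``Rigid3D`` registers every volume to volume 0.  Returned motion
    parameters have one 6-vector row per *retained* volume.
    """
    if run.n_volumes < 2:
        raise ValueError("need at least 2 volumes to motion-correct")
    if method == "NoMoCo":
        out = run.data[..., 1:].copy()
        params = np.zeros((run.n_volumes - 1, 6))
    elif method == "Rigid3D":
        ref = run.data[..., 0].astype(float)
        out = np.empty_like(run.data[..., 1:], dtype=float)
        params = np.zeros((run.n_volumes - 1, 6))
        prev = None
        for t in range(1, run.n_volumes):
            p, corrected = rigid_register(
                run.data[..., t].astype(float), ref, run.affine, x0=prev
            )
            params[t - 1] = p
            out[..., t - 1] = corrected
            prev = p
    else:
        raise ValueError(f"unknown motion-correction method: {method!r}")
    corrected_run = Bold4D(
        data=out, affine=run.affine, tr_seconds=run.tr_seconds, mask=run.mask
    )
    return corrected_run, params


def framewise_displacement(params: np.ndarray) -> np.ndarray:
    """Per-volume framewise displacement (mm) from six motion parameters.

    Sum of absolute backward differences of the six parameters, with the
    three rotations converted to arc length on a 50 mm sphere.  The
    first entry is 0 by convention.
    """
    p = np.atleast_2d(np.asarray(params, dtype=float))
    fd = np.zeros(p.shape[0])
    if p.shape[0] > 1:
        d = np.abs(np.diff(p, axis=0))
        rot_mm = d[:, :3].sum(axis=1) * (np.pi / 180.0) * FD_ROTATION_RADIUS_MM
        fd[1:] = rot_mm + d[:, 3:6].sum(axis=1)
    return fd


def smooth_in_mask(
    data: np.ndarray,
    fwhm_mm: float,
    mask: np.ndarray,
    voxel_size_mm: float,
) -> np.ndarray:
    """Gaussian smoothing restricted to a brain mask, with renormalization.

    Computes ``smooth(data * mask) / smooth(mask)`` so that no intensity
    leaks across the mask edge and constants are preserved exactly
    inside the mask; voxels outside the mask are zero.  ``fwhm_mm == 0``
    is the identity inside the mask.  Works on 3D fields and on 4D runs
    (volume-by-volume).
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be nonnegative")
    m = mask.astype(float)
    if not m.any():
        raise ValueError("empty mask")
    if data.ndim == 4:
        out = np.empty_like(data, dtype=float)
        for t in range(data.shape[3]):
            out[..., t] = smooth_in_mask(
                data[..., t], fwhm_mm, mask, voxel_size_mm
            )
        return out
    if fwhm_mm == 0:
        return data * m
    sigma_vox = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / voxel_size_mm
    num = ndimage.gaussian_filter(data * m, sigma_vox)
    den = ndimage.gaussian_filter(m, sigma_vox)
    out = np.zeros_like(num)
    inside = mask.astype(bool)
    out[inside] = num[inside] / den[inside]
    return out
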