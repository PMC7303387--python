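"""Voxelwise task regression: design construction and the five fit variants.

Variants: ``Std`` (ordinary least squares), ``REML`` (AR(1) prewhitened
least squares), ``Cen2``/``Cen5`` (volumes with framewise displacement
above 0.2 / 0.5 mm censored by row deletion), ``MPC`` (the six rigid
motion parameters added as nuisance covariates).

Every design carries the task regressors of all conditions of the run,
a Legendre polynomial baseline (order 1 below 150 volumes, order 2 at or
above, judged on the run's printed pre-removal volume count), and is
built for the volumes retained after the initial volume is dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import Bold4D
from .paradigm import TaskParadigm, condition_regressor

REGRESSION_VARIANTS = ("Std", "REML", "Cen2", "Cen5", "MPC")

POLY_ORDER_BREAK = 150  # volumes at/above which the baseline is quadratic
FD_STRICT_MM = 0.2
FD_LENIENT_MM = 0.5


@dataclass
class DesignMatrix:
    """Design for one run: baseline + task columns (+ motion), censor flags."""

    matrix: np.ndarray              # (n_retained, p)
    labels: list[str]
    task_columns: dict[str, int]    # condition label -> column index
    censored: np.ndarray            # bool per retained volume, True = drop
    variant: str

    @property
    def n_kept(self) -> int:
        return int((~self.censored).sum())

    def kept(self) -> np.ndarray:
        return self.matrix[~self.censored]


@dataclass
class StatMap:
    """One condition's t-map with the fit context needed downstream."""

    tmap: np.ndarray        # 3D, zero outside mask
    dof: int
    beta: np.ndarray        # 3D task-effect estimates
    residuals: np.ndarray   # 4D (x, y, z, kept volumes)
    mask: np.ndarray
    condition: str
    affine: np.ndarray


def censor_flags(fd: np.ndarray, threshold: float) -> np.ndarray:
    """True exactly where framewise displacement exceeds the threshold."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    return np.asarray(fd, dtype=float) > threshold


def _legendre_baseline(n: int, order: int) -> np.ndarray:
    x = np.linspace(-1.0, 1.0, n)
    return np.polynomial.legendre.legvander(x, order)


def build_design(
    paradigm: TaskParadigm,
    variant: str = "Std",
    motion: np.ndarray | None = None,
    fd: np.ndarray | None = None,
    drop_initial: int = 1,
) -> DesignMatrix:
    """Build the design for a run under one regression variant.

    `motion` and `fd` are per *retained* volume (after the initial
    volume removal), as produced by the preprocessing stage.  The
    polynomial-order rule uses the run's full printed volume count.
    """
    if variant not in REGRESSION_VARIANTS:
        raise ValueError(f"unknown regression variant: {variant!r}")
    n_total = paradigm.n_volumes
    n = n_total - drop_initial
    order = 1 if n_total < POLY_ORDER_BREAK else 2

    cols = [_legendre_baseline(n, order)]
    labels = [f"poly{k}" for k in range(order + 1)]
    task_columns = {}
    for cond in paradigm.condition_labels:
        reg = condition_regressor(paradigm, cond)[drop_initial:]
        task_columns[cond] = sum(c.shape[1] for c in cols)
        cols.append(reg[:, None])
        labels.append(cond)

    censored = np.zeros(n, dtype=bool)
    if variant == "MPC":
        if motion is None:
            raise ValueError("MPC requires motion parameters")
        motion = np.asarray(motion, dtype=float)
        if motion.shape != (n, 6):
            raise ValueError(f"motion must have shape ({n}, 6)")
        # demean (constant part is the baseline's job); drop flat columns
        mcols = motion - motion.mean(axis=0)
        keep_cols = mcols.std(axis=0) > 1e-12
        if keep_cols.any():
            cols.append(mcols[:, keep_cols])
            labels += [f"motion{k}" for k in np.where(keep_cols)[0]]
    elif variant in ("Cen2", "Cen5"):
        if fd is None:
            raise ValueError(f"{variant} requires a framewise-displacement series")
        thr = FD_STRICT_MM if variant == "Cen2" else FD_LENIENT_MM
        censored = censor_flags(np.asarray(fd)[:n], thr)

    X = np.hstack(cols)
    design = DesignMatrix(matrix=X, labels=labels, task_columns=task_columns,
                          censored=censored, variant=variant)
    Xk = design.kept()
    if np.linalg.matrix_rank(Xk) < Xk.shape[1]:
        raise ValueError("design matrix is rank deficient after censoring")
    return design


def _ols_core(Y: np.ndarray, X: np.ndarray):
    """Least squares of (T, V) data on (T, p) design; full-rank X assumed."""
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ Y
    resid = Y - X @ beta
    return beta, resid, XtX_inv


def _stat_maps_from_fit(bold, design, beta, resid, XtX_inv, dof):
    mask = bold.mask
    sigma2 = (resid ** 2).sum(axis=0) / dof
    maps = {}
    shape = mask.shape
    res4d = np.zeros(shape + (resid.shape[0],))
    res4d[mask] = resid.T
    for cond, k in design.task_columns.items():
        se = np.sqrt(sigma2 * XtX_inv[k, k])
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, beta[k] / se, 0.0)
        tmap = np.zeros(shape)
        tmap[mask] = t
        bmap = np.zeros(shape)
        bmap[mask] = beta[k]
        maps[cond] = StatMap(tmap=tmap, dof=dof, beta=bmap, residuals=res4d,
                             mask=mask, condition=cond, affine=bold.affine)
    return maps


def fit_ols(bold: Bold4D, design: DesignMatrix) -> dict[str, StatMap]:
    """Ordinary least squares per voxel; one StatMap per task condition.

    Censored volumes are removed from data and design before fitting;
    dof = retained volumes - design rank.
    """
    keep = ~design.censored
    X = design.matrix[keep]
    Y = bold.data[bold.mask][:, keep].T.astype(float)   # (T_kept, V)
    dof = X.shape[0] - X.shape[1]
    if dof <= 0:
        raise ValueError("nonpositive degrees of freedom")
    beta, resid, XtX_inv = _ols_core(Y, X)
    return _stat_maps_from_fit(bold, design, beta, resid, XtX_inv, dof)


def estimate_ar1(resid: np.ndarray) -> np.ndarray:
    """Lag-1 autocorrelation per column of a (T, V) residual array."""
    r = resid - resid.mean(axis=0)
    num = (r[1:] * r[:-1]).sum(axis=0)
    den = (r ** 2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = np.where(den > 0, num / den, 0.0)
    return rho


def _whiten(A: np.ndarray, rho: float) -> np.ndarray:
    """AR(1) prewhitening transform applied to the rows of A."""
    out = np.empty_like(A, dtype=float)
    out[0] = np.sqrt(1.0 - rho ** 2) * A[0]
    out[1:] = A[1:] - rho * A[:-1]
    return out


def fit_reml_ar1(
    bold: Bold4D, design: DesignMatrix, rho_bin: float = 0.01
) -> dict[str, StatMap]:
    """AR(1)-prewhitened least squares (Cochrane-Orcutt style).

    A first OLS pass estimates each voxel's lag-1 residual
    autocorrelation; estimates within sampling noise of zero
    (|rho| <= 2 / sqrt(T), the usual significance gate) are treated as
    white, the rest are binned on a `rho_bin` grid and each bin is
    prewhitened and refit.  Estimates at or beyond |rho| = 1 are
    clipped to 0.99 with a warning.  dof is adjusted by design rank
    only, as in standard prewhitened regression.
    """
    keep = ~design.censored
    if not keep.all():
        raise ValueError("AR(1) prewhitening expects an uncensored design")
    X = design.matrix
    Y = bold.data[bold.mask].T.astype(float)
    dof = X.shape[0] - X.shape[1]
    if dof <= 0:
        raise ValueError("nonpositive degrees of freedom")
    beta0, resid0, _ = _ols_core(Y, X)
    rho = estimate_ar1(resid0)
    if np.any(np.abs(rho) >= 1.0):
        warnings.warn("AR(1) estimate clipped to 0.99", RuntimeWarning)
        rho = np.clip(rho, -0.99, 0.99)
    rho_raw = rho.copy()
    gate = 2.0 / np.sqrt(X.shape[0])
    rho = np.where(np.abs(rho) > gate, rho, 0.0)
    rho_q = np.round(rho / rho_bin) * rho_bin

    beta = np.empty_like(beta0)
    resid = np.empty_like(resid0)
    XtX_inv_by_bin = {}
    for r in np.unique(rho_q):
        cols = np.where(rho_q == r)[0]
        Xw = _whiten(X, r)
        Yw = _whiten(Y[:, cols], r)
        b, res, XtX_inv = _ols_core(Yw, Xw)
        beta[:, cols] = b
        resid[:, cols] = res
        XtX_inv_by_bin[r] = XtX_inv

    # assemble per-condition maps with per-voxel variance factors
    mask = bold.mask
    shape = mask.shape
    sigma2 = (resid ** 2).sum(axis=0) / dof
    res4d = np.zeros(shape + (resid.shape[0],))
    res4d[mask] = resid.T
    maps = {}
    for cond, k in design.task_columns.items():
        ckk = np.empty(Y.shape[1])
        for r, XtX_inv in XtX_inv_by_bin.items():
            ckk[rho_q == r] = XtX_inv[k, k]
        se = np.sqrt(sigma2 * ckk)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, beta[k] / se, 0.0)
        tmap = np.zeros(shape)
        tmap[mask] = t
        bmap = np.zeros(shape)
        bmap[mask] = beta[k]
        sm = StatMap(tmap=tmap, dof=dof, beta=bmap, residuals=res4d,
                     mask=mask, condition=cond, affine=bold.affine)
        rho_map = np.zeros(shape)
        rho_map[mask] = rho_raw
        sm.rho = rho_map  # raw (ungated) AR(1) field, for diagnostics
        maps[cond] = sm
    return maps


def fit_variant(
    bold: Bold4D,
    design: DesignMatrix,
) -> dict[str, StatMap]:
    """Dispatch to the fitter implied by the design's variant."""
    if design.variant == "REML":
        return fit_reml_ar1(bold, design)
    return fit_ols(bold, design)
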