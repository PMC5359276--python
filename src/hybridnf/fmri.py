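"""Real-time fMRI processing: smoothing, ROI extraction, drift removal,
incremental GLM, activation mapping and feature extraction.

The incremental GLM keeps only the sufficient statistics (X'X, X'y, y'y, n)
of an ordinary least-squares fit, so absorbing one more scan costs O(p^2)
regardless of history length and the estimates at any scan count equal a
batch fit on the same rows.  Calibration runs the GLM over the whole
calibration series, converts the task-contrast t map to z, thresholds it
and keeps the 6-connected cluster with the highest peak statistic as the
feedback ROI.  Motion and slice-time correction are pass-through hooks: the
simulator generates motion-free data and replayed recordings are assumed
pre-corrected.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

from .core import CalibrationError, NoActiveClusterError, VolumeSeries
from .hemo import design_matrix

log = logging.getLogger(__name__)

FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))  # 2.3548


# ---------------------------------------------------------------------------
# pre-processing


def motion_correct(volume: np.ndarray, reference: np.ndarray | None = None) -> np.ndarray:
    """Pass-through hook for rigid-body motion correction."""
    return volume


def slice_time_correct(volume: np.ndarray, tr: float | None = None) -> np.ndarray:
    """Pass-through hook for slice-time correction."""
    return volume


def gaussian_smooth(volume: np.ndarray, fwhm: float,
                    voxel_sizes=(2.0, 2.0, 4.0)) -> np.ndarray:
    """Separable Gaussian smoothing with FWHM given in millimetres.

    sigma per axis = fwhm / 2.3548 / voxel size; fwhm = 0 is the identity.
    Nearest-edge boundary handling preserves constant fields everywhere.
    """
    if fwhm < 0:
        raise ValueError("fwhm must be >= 0")
    if fwhm == 0:
        return np.asarray(volume, float)
    sigmas = [fwhm / FWHM_TO_SIGMA / float(v) for v in voxel_sizes]
    return ndimage.gaussian_filter(np.asarray(volume, float), sigma=sigmas,
                                   mode="nearest")


def roi_mean(volume: np.ndarray, mask: np.ndarray) -> float:
    """Arithmetic mean of the masked voxels."""
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise CalibrationError("empty ROI mask: recalibrate before feedback")
    return float(np.asarray(volume, float)[mask].mean())


def background_mask(grid_shape: tuple) -> np.ndarray:
    """The top-slice background region used for global-signal accounting."""
    mask = np.zeros(grid_shape, dtype=bool)
    mask[..., -1] = True
    return mask


# ---------------------------------------------------------------------------
# temporal filtering


def detrend(series: np.ndarray, method: str = "linear", alpha: float = 0.05,
            causal: bool = False) -> np.ndarray:
    """Remove scanner drift from a scalar (or per-voxel) time series.

    ``linear`` subtracts the least-squares line; the causal variant refits
    on the growing prefix at every scan (residual k uses only scans <= k).
    ``ema`` subtracts a running exponential moving average with smoothing
    factor ``alpha`` (weight of the newest scan), initialized at the first
    value so the first residual is 0.
    """
    y = np.asarray(series, dtype=float)
    n = y.shape[0]
    if method == "linear":
        if n < 2:
            raise ValueError("linear detrend needs at least 2 scans")
        k = np.arange(n, dtype=float)
        if not causal:
            X = np.column_stack([np.ones(n), k])
            coef, *_ = np.linalg.lstsq(X, y.reshape(n, -1), rcond=None)
            fit = (X @ coef).reshape(y.shape)
            return y - fit
        out = np.zeros_like(y)
        sx = sxx = 0.0
        sy = np.zeros(y.shape[1:] if y.ndim > 1 else ())
        sxy = np.zeros_like(sy)
        for i in range(n):
            sx += i
            sxx += i * i
            sy = sy + y[i]
            sxy = sxy + i * y[i]
            m = i + 1
            det = m * sxx - sx * sx
            if det <= 0:
                out[i] = 0.0
            else:
                b = (m * sxy - sx * sy) / det
                a = (sy - b * sx) / m
                out[i] = y[i] - (a + b * i)
        return out
    if method == "ema":
        if not 0 < alpha <= 1:
            raise ValueError("ema smoothing alpha must lie in (0, 1]")
        out = np.zeros_like(y)
        m = y[0]
        out[0] = 0.0
        for i in range(1, n):
            m = (1.0 - alpha) * m + alpha * y[i]
            out[i] = y[i] - m
        return out
    raise ValueError(f"unknown detrend method {method!r}")


# ---------------------------------------------------------------------------
# incremental GLM


@dataclass
class GlmState:
    """Sufficient statistics of an OLS fit, updatable one scan at a time.

    ``xty`` and ``yty`` carry one column/entry per target series, so a
    whole volume (flattened to voxels) can be absorbed per update.
    """

    design_columns: list
    xtx: np.ndarray = None
    xty: np.ndarray = None
    yty: np.ndarray = None
    n: int = 0

    def __post_init__(self):
        p = len(self.design_columns)
        if self.xtx is None:
            self.xtx = np.zeros((p, p))
        if self.xty is None:
            self.xty = np.zeros((p, 0))

    @property
    def p(self) -> int:
        return len(self.design_columns)


def iglm_update(state: GlmState, x_row: np.ndarray, y) -> GlmState:
    """Absorb one scan: xtx += x x', xty += x y', yty += y^2, n += 1."""
    x = np.asarray(x_row, dtype=float).ravel()
    if x.size != state.p:
        raise ValueError(
            f"regressor row has {x.size} entries, design has {state.p} columns"
        )
    yv = np.atleast_1d(np.asarray(y, dtype=float)).ravel()
    if state.n == 0 and state.xty.shape[1] != yv.size:
        state.xty = np.zeros((state.p, yv.size))
        state.yty = np.zeros(yv.size)
    state.xtx += np.outer(x, x)
    state.xty += np.outer(x, yv)
    state.yty += yv * yv
    state.n += 1
    return state


@dataclass
class GlmEstimates:
    betas: np.ndarray          # (p, n_targets)
    sigma2: np.ndarray         # (n_targets,)
    dof: int
    tstats: dict = field(default_factory=dict)


def _name_collinear_columns(state: GlmState) -> list:
    """Columns whose removal restores full rank (small designs only)."""
    bad = []
    base_rank = np.linalg.matrix_rank(state.xtx)
    for j in range(state.p):
        keep = [i for i in range(state.p) if i != j]
        sub = state.xtx[np.ix_(keep, keep)]
        if np.linalg.matrix_rank(sub) == min(base_rank, len(keep)):
            bad.append(state.design_columns[j])
    return bad or list(state.design_columns)


def iglm_estimates(state: GlmState, contrasts: dict | None = None,
                   ridge_fallback: bool = True) -> GlmEstimates:
    """Betas, residual variance and optional contrast t statistics.

    beta = (X'X)^-1 X'y; sigma^2 = (y'y - beta' X'y) / (n - p);
    t = c'beta / sqrt(sigma^2 c'(X'X)^-1 c).  A singular X'X falls back to
    a tiny ridge (logged) unless disabled, in which case the error names
    the collinear columns.
    """
    if state.n <= state.p:
        raise ValueError(
            f"need more scans ({state.n}) than design columns ({state.p})"
        )
    xtx = state.xtx
    if np.linalg.cond(xtx) > 1e12:
        if not ridge_fallback:
            raise np.linalg.LinAlgError(
                "singular design cross-product; collinear columns: "
                + ", ".join(_name_collinear_columns(state))
            )
        lam = 1e-10 * np.trace(xtx) / state.p
        xtx = xtx + lam * np.eye(state.p)
        log.warning("near-singular X'X: ridge fallback applied (lambda=%.3g)", lam)
    xtx_inv = np.linalg.inv(xtx)
    betas = xtx_inv @ state.xty
    dof = state.n - state.p
    rss = state.yty - np.einsum("pt,pt->t", betas, state.xty)
    sigma2 = np.maximum(rss, 0.0) / dof
    est = GlmEstimates(betas=betas, sigma2=sigma2, dof=dof)
    for name, c in (contrasts or {}).items():
        c = np.asarray(c, dtype=float).ravel()
        num = c @ betas
        den2 = sigma2 * float(c @ xtx_inv @ c)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = num / np.sqrt(den2)
        t = np.where(den2 > 0, t, np.where(num > 0, np.inf,
                                           np.where(num < 0, -np.inf, 0.0)))
        est.tstats[name] = t
    return est


def t_to_z(t: np.ndarray, dof: int) -> np.ndarray:
    """Map t statistics to standard-normal quantiles (clipped for overflow)."""
    t = np.asarray(t, dtype=float)
    with np.errstate(over="ignore"):
        z = np.where(
            np.isfinite(t),
            stats.norm.isf(np.clip(stats.t.sf(t, dof), 1e-300, 1.0)),
            t,
        )
    return np.clip(z, -40.0, 40.0) if np.all(np.isfinite(z)) else z


# ---------------------------------------------------------------------------
# calibration: activation mapping and ROI selection


@dataclass
class ActivationMap:
    zmap: np.ndarray
    tmap: np.ndarray
    dof: int


@dataclass
class RoiMask:
    mask: np.ndarray
    label: str = "roi"

    def __post_init__(self):
        self.mask = np.asarray(self.mask, bool)

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


def glm_over_series(series: VolumeSeries, design: np.ndarray) -> GlmState:
    """Run the incremental GLM volume-by-volume over a whole series."""
    X, cols = design_matrix(design, series.tr)
    state = GlmState(design_columns=cols)
    flat = series.data.reshape(series.n_volumes, -1)
    for k in range(series.n_volumes):
        iglm_update(state, X[k], flat[k])
    return state


def activation_roi(
    series: VolumeSeries,
    design: np.ndarray,
    z_threshold: float = 3.0,
    min_cluster: int = 4,
) -> tuple:
    """Activation map + feedback ROI from a calibration series.

    Voxelwise task-contrast t values become z scores, thresholded at
    ``z_threshold``; 6-connected clusters of at least ``min_cluster``
    voxels compete on peak statistic (ties: larger cluster, then lowest
    linear voxel index).  Returns (ActivationMap, RoiMask).
    """
    grid = series.grid_shape
    state = glm_over_series(series, np.asarray(design, float))
    task = [0.0] * state.p
    task[state.design_columns.index("task")] = 1.0
    est = iglm_estimates(state, contrasts={"task": task})
    tmap = est.tstats["task"].reshape(grid)
    zmap = t_to_z(tmap, est.dof).reshape(grid)
    amap = ActivationMap(zmap=zmap, tmap=tmap, dof=est.dof)

    supra = zmap > z_threshold
    structure = ndimage.generate_binary_structure(3, 1)  # 6-connectivity
    labels, n_lab = ndimage.label(supra, structure=structure)
    best = None
    for lab in range(1, n_lab + 1):
        m = labels == lab
        size = int(m.sum())
        if size < min_cluster:
            continue
        peak = float(zmap[m].max())
        first = int(np.flatnonzero(m.ravel())[0])
        key = (peak, size, -first)
        if best is None or key > best[0]:
            best = (key, m)
    if best is None:
        raise NoActiveClusterError(
            f"no cluster of >= {min_cluster} voxels survived z > {z_threshold}; "
            "reduce the threshold or extend the calibration run"
        )
    return amap, RoiMask(best[1], label="calibration_roi")


# ---------------------------------------------------------------------------
# feature extraction


def fmri_feature(roi_signal: float, background_signal: float = 0.0,
                 mode: str = "background_subtracted") -> float:
    """ROI feedback feature: raw ROI mean or ROI minus background mean."""
    if not (np.isfinite(roi_signal) and np.isfinite(background_signal)):
        raise ValueError("ROI/background signals must be finite")
    if mode == "raw":
        return float(roi_signal)
    if mode == "background_subtracted":
        return float(roi_signal - background_signal)
    raise ValueError(f"unknown fMRI feature mode {mode!r}")
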