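"""Post-registration signal conditioning chain.

Fixed stage order: trim(6) -> band-pass -> trim(4) -> quadratic detrend ->
nuisance regression -> voxel-wise z-scoring.  On a 1,000-frame scan this
leaves 980 frames.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .core import VoxelTimeSeries

__all__ = [
    "ConditioningConfig",
    "trim_frames",
    "bandpass",
    "detrend_quadratic",
    "regress_nuisance",
    "zscore_voxels",
    "condition",
]

log = logging.getLogger(__name__)


@dataclass
class ConditioningConfig:
    trim_pre: int = 6
    band: tuple[float, float] = (0.01, 0.2)
    filter_order: int = 2  # applied forward-backward (zero phase)
    trim_post: int = 4
    detrend_order: int = 2
    nuisance: np.ndarray | None = None  # regressors x frames, post-trim length

    def validate(self, tr_seconds: float) -> None:
        low, high = self.band
        nyquist = 0.5 / tr_seconds
        if not (0 <= low < high < nyquist):
            raise ValueError(
                f"band {self.band} invalid for TR={tr_seconds}s (Nyquist {nyquist:.3f} Hz)"
            )
        if self.trim_pre < 0 or self.trim_post < 0:
            raise ValueError("trims must be >= 0")


def trim_frames(series: VoxelTimeSeries, n_each_end: int) -> VoxelTimeSeries:
    """Drop ``n_each_end`` frames from both ends of the scan."""
    if n_each_end < 0:
        raise ValueError("n_each_end must be >= 0")
    if n_each_end == 0:
        return series.with_data(series.data.copy())
    if series.n_frames <= 2 * n_each_end:
        raise ValueError(
            f"cannot trim {n_each_end} frames from each end of a "
            f"{series.n_frames}-frame scan"
        )
    return series.with_data(series.data[:, n_each_end:-n_each_end])


def bandpass(series: VoxelTimeSeries, cfg: ConditioningConfig) -> VoxelTimeSeries:
    """Zero-phase Butterworth band-pass of every voxel trace."""
    cfg.validate(series.tr_seconds)
    fs = 1.0 / series.tr_seconds
    sos = sps.butter(cfg.filter_order, cfg.band, btype="bandpass", fs=fs, output="sos")
    filtered = sps.sosfiltfilt(sos, series.data, axis=1)
    return series.with_data(filtered)


def detrend_quadratic(series: VoxelTimeSeries, order: int = 2) -> VoxelTimeSeries:
    """Remove the least-squares polynomial trend (default quadratic) per voxel."""
    T = series.n_frames
    if T < order + 1:
        raise ValueError(f"need at least {order + 1} frames for order-{order} detrend")
    t = np.arange(T, dtype=float)
    basis = np.vander(t, order + 1, increasing=True)  # columns 1, t, t^2, ...
    coef, *_ = np.linalg.lstsq(basis, series.data.T, rcond=None)
    residual = series.data - (basis @ coef).T
    return series.with_data(residual)


def regress_nuisance(
    series: VoxelTimeSeries, regressors: np.ndarray
) -> VoxelTimeSeries:
    """Project out span{1, regressors} from every voxel trace (OLS)."""
    R = np.atleast_2d(np.asarray(regressors, dtype=float))
    if R.shape[1] != series.n_frames:
        if R.shape[0] == series.n_frames:
            R = R.T
        else:
            raise ValueError("regressor length does not match frame count")
    X = np.column_stack([np.ones(series.n_frames), R.T])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        log.warning("rank-deficient nuisance regressors (rank %d < %d); "
                    "using pseudoinverse", rank, X.shape[1])
    beta = np.linalg.pinv(X) @ series.data.T
    residual = series.data - (X @ beta).T
    return series.with_data(residual)


def zscore_voxels(
    series: VoxelTimeSeries, atol: float = 1e-12
) -> tuple[VoxelTimeSeries, np.ndarray]:
    """Normalise each voxel trace to mean 0, sample (ddof=1) variance 1.

    Zero-variance voxels cannot be normalised; they are dropped from the
    mask and their row indices returned so the caller can log/propagate
    the exclusion.
    """
    mu = series.data.mean(axis=1, keepdims=True)
    sd = series.data.std(axis=1, ddof=1, keepdims=True)
    degenerate = np.flatnonzero(sd[:, 0] <= atol)
    if degenerate.size:
        log.warning("excluding %d zero-variance voxels from mask: %s",
                    degenerate.size, degenerate[:20])
        keep = np.setdiff1d(np.arange(series.n_voxels), degenerate)
        series = series.subset_voxels(keep)
        mu, sd = mu[keep], sd[keep]
    z = (series.data - mu) / sd
    return series.with_data(z), degenerate


def condition(
    series: VoxelTimeSeries, cfg: ConditioningConfig | None = None
) -> tuple[VoxelTimeSeries, np.ndarray]:
    """Run the full chain in its fixed order; returns (series, excluded voxels)."""
    cfg = cfg or ConditioningConfig()
    out = trim_frames(series, cfg.trim_pre)
    log.info("%s: trimmed %d -> %d frames", series.subject_id,
             series.n_frames, out.n_frames)
    out = bandpass(out, cfg)
    out = trim_frames(out, cfg.trim_post)
    log.info("%s: post-filter trim -> %d frames", series.subject_id, out.n_frames)
    out = detrend_quadratic(out, cfg.detrend_order)
    if cfg.nuisance is not None:
        out = regress_nuisance(out, cfg.nuisance)
    return zscore_voxels(out)
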