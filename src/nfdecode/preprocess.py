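"""Streaming and batch preprocessing: smoothing, masking, linear detrending.

The real-time path processes one volume at a time: spatial Gaussian
smoothing, brain masking, then incremental per-voxel linear detrending.
The incremental detrend keeps only constant-size running sums
(n, Σt, Σt², Σy, Σty per voxel) yet reproduces, at every step n, the
step-n residual of an ordinary-least-squares line fitted to all n
samples seen so far — so the streaming path converges to the batch
detrend used when preparing training data offline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "fwhm_to_sigma",
    "smooth",
    "smooth_run",
    "apply_mask",
    "mask_order",
    "unmask",
    "DetrendState",
    "batch_detrend",
]

#: FWHM = 2 * sqrt(2 ln 2) * sigma
_FWHM_FACTOR = 2.0 * np.sqrt(2.0 * np.log(2.0))


def fwhm_to_sigma(fwhm_mm: float, voxel_mm: float) -> float:
    """Gaussian sigma in voxel units for a kernel of given FWHM in mm."""
    if fwhm_mm <= 0 or voxel_mm <= 0:
        raise ValueError("fwhm_mm and voxel_mm must be > 0")
    return fwhm_mm / (_FWHM_FACTOR * voxel_mm)


def smooth(volume: np.ndarray, fwhm_mm: float = 8.0, voxel_mm: float = 3.0) -> np.ndarray:
    """Separable 3D Gaussian smoothing with reflecting boundaries.

    Reflection preserves total mass on the small grids used here, so a
    constant field passes through unchanged.
    """
    sigma = fwhm_to_sigma(fwhm_mm, voxel_mm)
    return ndimage.gaussian_filter(
        np.asarray(volume, dtype=np.float64), sigma=sigma, mode="reflect"
    )


def smooth_run(data4d: np.ndarray, fwhm_mm: float = 8.0, voxel_mm: float = 3.0) -> np.ndarray:
    """Smooth every volume of a 4D (x, y, z, t) array spatially.

    Volumes are independent, so this equals applying :func:`smooth` to
    each volume; the single filtered pass is just faster.
    """
    sigma = fwhm_to_sigma(fwhm_mm, voxel_mm)
    return ndimage.gaussian_filter(
        np.asarray(data4d, dtype=np.float64),
        sigma=(sigma, sigma, sigma, 0.0),
        mode="reflect",
    )


def mask_order(mask: np.ndarray) -> np.ndarray:
    """Flat (C-order) indices of the in-mask voxels — the fixed row order."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask selects no voxels")
    return np.flatnonzero(mask.ravel(order="C"))


def apply_mask(data: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Extract in-mask voxels as a features x volumes matrix.

    ``data`` is either a 3D volume (returns a vector) or a 4D run
    (returns a matrix whose rows follow :func:`mask_order`).
    """
    mask = np.asarray(mask, dtype=bool)
    data = np.asarray(data)
    if data.shape[: mask.ndim] != mask.shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match data grid "
            f"{data.shape[:mask.ndim]}"
        )
    order = mask_order(mask)
    flat = data.reshape(mask.size, -1)
    out = flat[order]
    return out[:, 0] if data.ndim == mask.ndim else out


def unmask(values: np.ndarray, mask: np.ndarray, fill: float = 0.0) -> np.ndarray:
    """Scatter a per-voxel vector back onto the 3D grid (out-of-mask = fill)."""
    mask = np.asarray(mask, dtype=bool)
    values = np.asarray(values, dtype=np.float64)
    if values.shape[0] != int(mask.sum()):
        raise ValueError("value count does not match mask voxel count")
    grid = np.full(mask.shape, fill, dtype=np.float64)
    grid[mask] = values
    return grid


class DetrendState:
    """Constant-memory streaming linear detrend over many voxels at once.

    Maintains running sums of a least-squares line fit per voxel with
    1-based time index t.  ``update(y_t)`` ingests one volume's values
    and returns the residuals of the cumulative OLS fit at the current
    step; with fewer than three samples a line fits the data exactly, so
    the warm-up residual is 0.

    ``window`` switches to a sliding-window fit over the last ``window``
    samples (memory then grows with the window, not with n).

    ``min_samples`` delays the line fit: until that many samples have
    arrived, the state emits de-meaned values (``y - running mean``)
    instead of OLS residuals.  Early in a run the cumulative fit cannot
    separate slow drift from the block structure and would absorb task
    signal into the slope; de-meaning is the safe fallback because drift
    is negligible over a few blocks.  The default of 3 starts the exact
    cumulative fit as soon as it is defined.
    """

    def __init__(
        self,
        n_voxels: int,
        window: int | None = None,
        min_samples: int = 3,
    ):
        if n_voxels < 1:
            raise ValueError("n_voxels must be >= 1")
        if window is not None and window < 3:
            raise ValueError("window must be >= 3")
        if min_samples < 3:
            raise ValueError("min_samples must be >= 3")
        self.n_voxels = n_voxels
        self.window = window
        self.min_samples = min_samples
        self.reset()

    def reset(self) -> None:
        self.n = 0
        self._auto_t = 0.0
        self._st = 0.0
        self._stt = 0.0
        self._sy = np.zeros(self.n_voxels)
        self._sty = np.zeros(self.n_voxels)
        self._buffer: list[tuple[float, np.ndarray]] = []  # window mode only

    def _check(self, y_t: np.ndarray) -> np.ndarray:
        y_t = np.asarray(y_t, dtype=np.float64)
        if y_t.shape != (self.n_voxels,):
            raise ValueError(
                f"expected {self.n_voxels} values, got shape {y_t.shape}"
            )
        if not np.all(np.isfinite(y_t)):
            raise ValueError("non-finite input to detrend_update")
        return y_t

    def _fit_residual(self, y: np.ndarray, t: float) -> np.ndarray:
        """Residual of ``y`` at time ``t`` under the current fit."""
        n = len(self._buffer) if self.window is not None else self.n
        if n == 0:
            return y.copy()
        st, stt, sy, sty = self._st, self._stt, self._sy, self._sty
        if n <= 2 or self.n < self.min_samples:
            # a line through <=2 points fits them exactly (residual 0 on
            # ingested points); for evaluation, fall back to de-meaning
            return y - sy / n
        denom = n * stt - st * st
        slope = (n * sty - st * sy) / denom
        intercept = (sy - slope * st) / n
        return y - (intercept + slope * t)

    def update(self, y_t: np.ndarray, t: float | None = None) -> np.ndarray:
        """Ingest one volume; return per-voxel residuals at this step.

        ``t`` defaults to an internal 1-based counter; pass an explicit
        time (e.g. the acquisition volume number) when the state is
        updated on a subset of volumes, so the fitted line lives on the
        acquisition time axis.
        """
        y_t = self._check(y_t)
        if t is None:
            t = self._auto_t + 1.0
        t = float(t)
        self._auto_t = t
        self.n += 1

        if self.window is not None:
            self._buffer.append((t, y_t))
            if len(self._buffer) > self.window:
                t0, y0 = self._buffer.pop(0)
                self._st -= t0
                self._stt -= t0 * t0
                self._sy -= y0
                self._sty -= t0 * y0
        self._st += t
        self._stt += t * t
        self._sy += y_t
        self._sty += t * y_t

        n = len(self._buffer) if self.window is not None else self.n
        if n <= 2:
            return np.zeros(self.n_voxels)
        return self._fit_residual(y_t, t)

    def evaluate(self, y: np.ndarray, t: float) -> np.ndarray:
        """Residual of ``y`` at time ``t`` without ingesting it.

        Lets the closed-loop path fit the baseline drift on rest-cue
        volumes only and still correct every volume: the line never sees
        task signal, so it cannot absorb it into the slope.
        """
        return self._fit_residual(self._check(y), float(t))


def batch_detrend(series: np.ndarray, axis: int = -1) -> np.ndarray:
    """Residuals of a single OLS line fit over a full series.

    Works on any array with time along ``axis``; residuals have zero
    mean along that axis.  Used offline to prepare training features.
    """
    series = np.asarray(series, dtype=np.float64)
    n = series.shape[axis]
    if n < 3:
        raise ValueError(f"need at least 3 samples to detrend, got {n}")
    y = np.moveaxis(series, axis, -1)
    t = np.arange(1.0, n + 1.0)
    t_c = t - t.mean()
    y_mean = y.mean(axis=-1, keepdims=True)
    slope = (y - y_mean) @ t_c / (t_c @ t_c)
    resid = y - y_mean - slope[..., None] * t_c
    return np.moveaxis(resid, -1, axis)
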