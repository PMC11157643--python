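"""Sliding-window preprocessing of an LC-MS run.

The region of interest of the chromatogram is partitioned into short,
overlapping retention-time slices.  Within each slice the profile spectra
are resampled onto one uniform m/z grid, averaged point-wise, baseline
subtracted, and Gaussian smoothed — in that fixed order — producing one
clean spectrum per slice ready for charge-state deconvolution.

The baseline estimator is asymmetric least squares (AsLS): a smoothness-
penalized fit that is pulled far more strongly towards points *below* it
than above, so it tracks the broad unresolved hump (attributed to a
multitude of low-abundance co-eluting Fab clones) while passing underneath
resolved charge-state peaks.  The single user-facing knob is ``flatness``
in (0, 1], mapped log-linearly to the estimator's length scale over
[10 Th, 1000 Th]; higher flatness gives a stiffer, flatter baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import solveh_banded
from scipy.ndimage import gaussian_filter1d

from .errors import ConfigError
from .io import PipelineConfig, Run, Spectrum, mz_grid

__all__ = [
    "SliceWindow",
    "make_slices",
    "average_slice",
    "subtract_baseline",
    "smooth",
    "preprocess_slice",
]

# FWHM of a Gaussian = 2*sqrt(2*ln 2) * sigma
FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))

_EPS = 1e-9


@dataclass(frozen=True)
class SliceWindow:
    """One retention-time slice: half-open [rt_start, rt_end), the final
    window of the region of interest being closed at roi_end."""

    index: int
    rt_start: float
    rt_end: float
    is_last: bool = False

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.rt_start + self.rt_end)

    def contains(self, rt: float) -> bool:
        if self.is_last:
            return self.rt_start - _EPS <= rt <= self.rt_end + _EPS
        return self.rt_start - _EPS <= rt < self.rt_end - _EPS


def make_slices(roi_start: float, roi_end: float, slice_width: float,
                slice_overlap: float) -> list[SliceWindow]:
    """Partition [roi_start, roi_end] into overlapping slice windows.

    Window ``k`` starts at ``roi_start + k*(slice_width - slice_overlap)``;
    generation stops once coverage reaches ``roi_end`` and the final window
    is clipped there, so the union of windows covers the region of interest
    exactly.  A region shorter than one window yields a single clipped
    window.
    """
    if not roi_start < roi_end:
        raise ConfigError("roi_start: roi_start must be < roi_end")
    if not 0 < slice_overlap < slice_width:
        raise ConfigError("slice_overlap: must satisfy 0 < overlap < slice_width")
    stride = slice_width - slice_overlap
    windows: list[SliceWindow] = []
    k = 0
    while True:
        start = roi_start + k * stride
        end = start + slice_width
        clipped = end >= roi_end - _EPS
        windows.append(SliceWindow(index=k, rt_start=start,
                                   rt_end=min(end, roi_end), is_last=clipped))
        if clipped:
            break
        k += 1
    return windows


def average_slice(run: Run, window: SliceWindow, config: PipelineConfig) -> Spectrum:
    """Point-wise mean spectrum of all scans falling inside the window.

    Scans are linearly resampled onto the uniform config m/z grid first so
    that averaging is well defined even if the instrument grid drifts.  An
    empty window yields an all-zero spectrum (flagged by its zero total),
    which downstream stages skip.
    """
    grid = mz_grid(config)
    acc = np.zeros_like(grid)
    n = 0
    for scan in run.scans:
        if not window.contains(scan.rt):
            continue
        if scan.mz.size == grid.size and np.array_equal(scan.mz, grid):
            acc += scan.intensity
        else:
            acc += np.interp(grid, scan.mz, scan.intensity, left=0.0, right=0.0)
        n += 1
    if n:
        acc /= n
    return Spectrum(rt=window.midpoint, mz=grid, intensity=acc)


def _baseline_length_scale(flatness: float) -> float:
    """Map flatness in (0, 1] log-linearly onto [10 Th, 1000 Th]."""
    return 10.0 ** (1.0 + 2.0 * flatness)


def estimate_baseline(spectrum: Spectrum, flatness: float,
                      asymmetry: float = 0.1, n_iter: int = 10) -> np.ndarray:
    """Asymmetric-least-squares baseline estimate.

    Minimizes ``sum_i w_i (y_i - b_i)^2 + lam * sum_i (D2 b)_i^2`` where the
    weights are ``asymmetry`` for points below the current baseline estimate
    (peaks) and ``1 - asymmetry`` above it, re-evaluated for ``n_iter``
    rounds.  The stiffness ``lam = (L / (2 pi dx))**4`` places the
    smoother's cut-off at the flatness-controlled length scale ``L``:
    structure much broader than ``L`` is followed, structure much narrower
    (resolved peaks) is not.  Under regions flagged as peak the effective
    stiffness grows by ``1/asymmetry``; the default 0.1 keeps the effective
    cut-off below the width of the broad unresolved hump so the hump is
    tracked to a few percent while isolated charge-state peaks (a thousand
    times narrower) are passed under essentially untouched.
    """
    if not 0 < flatness <= 1:
        raise ConfigError("baseline_flatness: must lie in (0, 1]")
    y = spectrum.intensity
    n = y.size
    if n < 5 or not np.any(y):
        return np.zeros_like(y)
    dx = float(np.median(np.diff(spectrum.mz)))
    scale_l = _baseline_length_scale(flatness)
    lam = (scale_l / (2.0 * np.pi * dx)) ** 4

    # lam * D2.T @ D2 (D2 = second difference) is pentadiagonal; store it in
    # scipy's upper banded form: row 0 = +2 diagonal, row 1 = +1, row 2 = main.
    diag = np.full(n, 6.0 * lam)
    diag[[0, -1]] = lam
    diag[[1, -2]] = 5.0 * lam
    off1 = np.full(n - 1, -4.0 * lam)
    off1[[0, -1]] = -2.0 * lam
    ab_penalty = np.zeros((3, n))
    ab_penalty[0, 2:] = lam
    ab_penalty[1, 1:] = off1
    ab_penalty[2, :] = diag

    w = np.ones(n)
    b = y.copy()
    for _ in range(n_iter):
        ab = ab_penalty.copy()
        ab[2, :] += w
        b = solveh_banded(ab[:, :], w * y, lower=False)
        w_new = np.where(y > b, asymmetry, 1.0 - asymmetry)
        if np.array_equal(w_new, w):
            break
        w = w_new
    return b


def subtract_baseline(spectrum: Spectrum, flatness: float) -> Spectrum:
    """Subtract the AsLS baseline estimate, clipping the result at zero."""
    baseline = estimate_baseline(spectrum, flatness)
    corrected = np.clip(spectrum.intensity - baseline, 0.0, None)
    return Spectrum(rt=spectrum.rt, mz=spectrum.mz, intensity=corrected)


def smooth(spectrum: Spectrum, width: float, iterations: int = 1) -> Spectrum:
    """Gaussian smoothing; ``width`` is the kernel FWHM in Th.

    The kernel standard deviation is ``width / 2.3548`` (FWHM-to-sigma),
    applied ``iterations`` times.  Zero iterations is the identity.  Total
    intensity is conserved away from the grid edges.
    """
    if width <= 0:
        raise ConfigError("smooth_width: must be > 0")
    if iterations < 0:
        raise ConfigError("smooth_iterations: must be >= 0")
    if iterations == 0 or spectrum.intensity.size < 2:
        return Spectrum(rt=spectrum.rt, mz=spectrum.mz,
                        intensity=spectrum.intensity.copy())
    dx = float(np.median(np.diff(spectrum.mz)))
    sigma = width / FWHM_TO_SIGMA / dx
    out = spectrum.intensity
    for _ in range(iterations):
        out = gaussian_filter1d(out, sigma=sigma, mode="constant", cval=0.0,
                                truncate=6.0)
    return Spectrum(rt=spectrum.rt, mz=spectrum.mz, intensity=out)


def preprocess_slice(run: Run, window: SliceWindow,
                     config: PipelineConfig) -> Spectrum | None:
    """Average → baseline-subtract → smooth one slice; None if it is empty."""
    averaged = average_slice(run, window, config)
    if not np.any(averaged.intensity):
        return None
    corrected = subtract_baseline(averaged, config.baseline_flatness)
    return smooth(corrected, config.smooth_width, config.smooth_iterations)
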