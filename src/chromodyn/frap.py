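"""3D-FRAP measurement pipeline.

Fluorescence recovery after photobleaching of a chromocenter is measured
from three per-frame intensity series (chromocenter, whole nucleus,
background), corrected for background and for acquisition photobleaching,
averaged over cells, and summarized as bleach depth I_min, maximal
recovery I_max and time to half-recovery t_1/2.

The correction is the classical double-normalization: background is
subtracted from both the chromocenter and nucleus series, each is
normalized to its own pre-bleach mean, and the chromocenter curve is
divided frame by frame by the nucleus curve.  Any multiplicative decay
shared by the two series (acquisition photobleaching) cancels exactly.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Callable, Sequence

import numpy as np
from scipy import stats

log = logging.getLogger("chromodyn")


@dataclasses.dataclass
class FRAPSeries:
    """Raw per-frame intensities around a chromocenter bleach event.

    The bleach occurs between frame ``n_pre - 1`` and frame ``n_pre``.
    ``initial_chromo_intensity`` is the absolute pre-bleach chromocenter
    mean, used downstream as an expression-level proxy.
    """

    times: np.ndarray
    chromo_raw: np.ndarray
    nucleus_raw: np.ndarray
    background_raw: np.ndarray
    n_pre: int = 5
    cell_id: str = "cell"
    initial_chromo_intensity: float = float("nan")

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.chromo_raw = np.asarray(self.chromo_raw, float)
        self.nucleus_raw = np.asarray(self.nucleus_raw, float)
        self.background_raw = np.asarray(self.background_raw, float)
        n = len(self.times)
        if not (len(self.chromo_raw) == len(self.nucleus_raw)
                == len(self.background_raw) == n):
            raise ValueError("all series must have equal length")
        if not 1 <= self.n_pre < n:
            raise ValueError("need 1 <= n_pre < number of frames")
        if np.isnan(self.initial_chromo_intensity):
            self.initial_chromo_intensity = float(
                self.chromo_raw[: self.n_pre].mean())


@dataclasses.dataclass(frozen=True)
class FRAPSummary:
    """Bleach depth, maximal recovery and time to half-recovery (s)."""

    i_min: float
    i_max: float
    t_half: float

    def __post_init__(self) -> None:
        if self.i_min > self.i_max + 1e-12:
            raise ValueError("i_min must not exceed i_max")
        if self.t_half < 0:
            raise ValueError("t_half must be nonnegative")


class ExcludedCellError(ValueError):
    """Raised when a cell fails the positive-nuclear-signal requirement."""


def project_and_measure(stack: np.ndarray, chromo_mask: np.ndarray,
                        nucleus_mask: np.ndarray, background_mask: np.ndarray,
                        times: np.ndarray, n_pre: int = 5,
                        cell_id: str = "cell") -> FRAPSeries:
    """Measure a FRAPSeries from a toy (T, Z, Y, X) movie.

    Each frame's Z-planes are summed and the mean of the summed image is
    taken within each mask.  The chromocenter mask is a union ROI covering
    the chromocenter's whole track over Z and time.
    """
    stack = np.asarray(stack, float)
    if stack.ndim == 3:  # (T, Y, X) single-plane movie
        stack = stack[:, None]
    if stack.ndim != 4:
        raise ValueError("stack must be (T, Z, Y, X) or (T, Y, X)")
    series = []
    for mask in (chromo_mask, nucleus_mask, background_mask):
        mask = np.asarray(mask, bool)
        if mask.shape != stack.shape[2:]:
            raise ValueError("mask shape must match the frame XY shape")
        if not mask.any():
            raise ValueError("empty mask")
        zsum = stack.sum(axis=1)  # (T, Y, X)
        series.append(zsum[:, mask].mean(axis=1))
    chromo, nucleus, background = series
    return FRAPSeries(times=np.asarray(times, float), chromo_raw=chromo,
                      nucleus_raw=nucleus, background_raw=background,
                      n_pre=n_pre, cell_id=cell_id)


def correct_series(series: FRAPSeries) -> np.ndarray:
    """Background-subtract, pre-bleach-normalize and bleach-correct.

    Returns the corrected recovery curve c(t); its pre-bleach mean is 1 by
    construction.  Raises :class:`ExcludedCellError` if the background-
    subtracted nuclear signal is not strictly positive at every frame
    (such cells are excluded from averaging, mirroring the exclusion of
    cells with excessive movement).
    """
    n_pre = series.n_pre
    chromo = series.chromo_raw - series.background_raw
    nucleus = series.nucleus_raw - series.background_raw
    if np.any(nucleus <= 0):
        raise ExcludedCellError(
            f"cell {series.cell_id}: nonpositive corrected nuclear signal")
    chromo_n = chromo / chromo[:n_pre].mean()
    nucleus_n = nucleus / nucleus[:n_pre].mean()
    return chromo_n / nucleus_n


def correct_cells(cells: Sequence[FRAPSeries]):
    """Correct a list of cells, dropping excluded ones.

    Returns ``(curves, kept, n_excluded)`` where ``curves`` is an
    (n_kept, n_frames) array and ``kept`` the retained FRAPSeries.
    """
    curves, kept, n_excluded = [], [], 0
    for s in cells:
        try:
            curves.append(correct_series(s))
            kept.append(s)
        except ExcludedCellError as err:
            log.warning("%s", err)
            n_excluded += 1
    return np.asarray(curves), kept, n_excluded


def _smooth_same(y: np.ndarray, smooth: int) -> np.ndarray:
    """Centered moving average; endpoints where the window does not fit are
    left unsmoothed."""
    if smooth <= 1 or len(y) < smooth:
        return y
    out = y.copy()
    kernel = np.ones(smooth) / smooth
    half = smooth // 2
    out[half: len(y) - half] = np.convolve(y, kernel, mode="valid")
    return out


def average_and_summarize(curves: np.ndarray, times: np.ndarray,
                          n_pre: int = 5, smooth: int = 3,
                          tail_s: float = 30.0):
    """Average corrected curves and summarize the mean recovery.

    I_min is the mean-curve value at the first post-bleach frame (not the
    global minimum).  I_max, the maximal recovery, is the mean of the
    ``smooth``-frame moving average of the post-bleach curve over its
    final ``tail_s`` seconds — for a monotone recovery this coincides
    with the curve's maximum while avoiding the upward bias a noisy
    maximum would carry.  t_1/2 is the time (from the first post-bleach
    frame) at which the smoothed mean curve first crosses the half level
    I_min + (I_max - I_min)/2, located by linear interpolation between
    frames.

    Returns ``(mean_curve, sd_curve, FRAPSummary)``.
    """
    curves = np.atleast_2d(np.asarray(curves, float))
    times = np.asarray(times, float)
    if curves.shape[0] < 1 or curves.shape[1] != len(times):
        raise ValueError("need >= 1 curve on a common time base")
    if n_pre >= len(times):
        raise ValueError("no post-bleach frames")
    mean = curves.mean(axis=0)
    sd = curves.std(axis=0, ddof=1) if curves.shape[0] > 1 else np.zeros_like(mean)

    post = mean[n_pre:]
    t_post = times[n_pre:] - times[n_pre]
    i_min = float(post[0])
    smoothed = _smooth_same(post, smooth)
    tail = smoothed[t_post >= t_post[-1] - tail_s]
    i_max = float(max(tail.mean(), i_min))
    half = i_min + 0.5 * (i_max - i_min)
    above = smoothed >= half
    if above[0] or i_max == i_min:
        t_half = 0.0
    elif not above.any():
        t_half = float(t_post[-1])  # never crosses within the record
    else:
        j = int(np.argmax(above))
        # linear interpolation between frames j-1 and j
        frac = (half - smoothed[j - 1]) / (smoothed[j] - smoothed[j - 1])
        t_half = float(t_post[j - 1] + frac * (t_post[j] - t_post[j - 1]))
    return mean, sd, FRAPSummary(i_min=i_min, i_max=i_max, t_half=t_half)


def _early_recovery_mean(curve: np.ndarray, times: np.ndarray, n_pre: int,
                         window_s: float = 60.0) -> float:
    t_post = times[n_pre:] - times[n_pre]
    post = curve[n_pre:]
    return float(post[t_post <= window_s].mean())


def compare_recovery(curves_a: np.ndarray, curves_b: np.ndarray,
                     times: np.ndarray, n_pre: int = 5,
                     alternative: str = "less",
                     scalar: str | Callable = "early_mean",
                     window_s: float = 60.0):
    """Mann-Whitney U comparison of two groups of corrected curves.

    Each cell is reduced to a scalar (default: mean corrected intensity
    over the first ``window_s`` seconds after the bleach) and the two
    scalar samples are compared with a rank-sum test.  Exact p-values are
    used for group sizes <= 20, the tie-corrected normal approximation
    otherwise.  Returns ``(U, p)``.
    """
    curves_a = np.atleast_2d(curves_a)
    curves_b = np.atleast_2d(curves_b)
    if min(len(curves_a), len(curves_b)) < 3:
        raise ValueError("each group needs >= 3 cells")
    if callable(scalar):
        reduce = scalar
    elif scalar == "early_mean":
        reduce = lambda c: _early_recovery_mean(c, times, n_pre, window_s)
    elif scalar == "i_min":
        reduce = lambda c: float(c[n_pre])
    else:
        raise ValueError(f"unknown scalar {scalar!r}")
    a = np.array([reduce(c) for c in curves_a])
    b = np.array([reduce(c) for c in curves_b])
    method = "exact" if max(len(a), len(b)) <= 20 else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)
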