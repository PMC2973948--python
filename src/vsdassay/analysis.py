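"""Fluorescence analysis pipeline of the VSD assay.

Operations: dF/F0 extraction from a ROI of a frame stack, noise-referenced
peak detection (events are runs of at least ``min_duration`` frames strictly
above ``k`` baseline standard deviations), half-width estimation with a
single-exponential fit to the repolarization, the labeling-specificity
statistic N_roi/N_im, 8-bit contrast normalization, and firing / non-firing
cell classification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .errors import (
    ConfigurationError,
    DataError,
    DegenerateRangeError,
    DomainError,
    UndefinedStatisticError,
)
from .imaging import FrameStack

__all__ = [
    "ROI",
    "FluorescenceTrace",
    "PeakEvent",
    "DetectionResult",
    "HalfWidthResult",
    "compute_dff",
    "detect_peaks",
    "half_width",
    "labeling_specificity",
    "normalize_to_8bit",
    "classify_cells",
]

DEFAULT_BASELINE_WINDOW = (0, 50)   # frames, pre-stimulus
DEFAULT_SEARCH_FRAMES = 100         # post-stimulus detection window


@dataclass
class ROI:
    """A set of pixels within an image shape, stored as a boolean mask."""

    mask: np.ndarray

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise DomainError("ROI is empty")

    @classmethod
    def from_pixels(cls, pixels, shape) -> "ROI":
        mask = np.zeros(shape, dtype=bool)
        rows, cols = np.asarray(pixels).T
        if rows.max() >= shape[0] or cols.max() >= shape[1] or rows.min() < 0 or cols.min() < 0:
            raise DomainError("ROI pixel indices out of bounds")
        mask[rows, cols] = True
        return cls(mask)

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


@dataclass
class FluorescenceTrace:
    """dF/F0 time series for one ROI."""

    times: np.ndarray            # ms
    dff: np.ndarray              # fractional dF/F0
    f0: float                    # counts
    baseline_window: tuple[int, int]

    def __post_init__(self):
        if self.f0 <= 0:
            raise DataError("baseline fluorescence F0 must be positive")
        if len(self.times) != len(self.dff):
            raise DataError("times and dff must have equal length")


@dataclass
class PeakEvent:
    onset_frame: int
    peak_frame: int
    amplitude: float             # dF/F0 at the peak frame
    end_frame: int


@dataclass
class DetectionResult:
    """Per-cell outcome of the firing classification."""

    cell_id: int
    has_peak: bool
    peak_amplitude: float | None
    half_width_ms: float | None
    noise_sd: float
    half_width_method: str | None = None


@dataclass
class HalfWidthResult:
    hw_ms: float
    method: str                  # 'exponential' or 'interpolated' (fallback)
    t_rise: float
    t_fall: float
    tau_ms: float | None = None

    def __float__(self) -> float:
        return self.hw_ms


def compute_dff(
    stack: FrameStack,
    roi: ROI,
    baseline_window: tuple[int, int] = DEFAULT_BASELINE_WINDOW,
) -> FluorescenceTrace:
    """Per-frame ROI mean F(t); F0 = mean F over the baseline window;
    dff = (F - F0) / F0.  Scale-invariant by construction."""
    if roi.mask.shape != stack.frames.shape[1:]:
        raise DataError("ROI shape does not match the frame shape")
    lo, hi = baseline_window
    if not 0 <= lo < hi <= stack.n_frames:
        raise DataError(f"baseline window {baseline_window} invalid for "
                        f"{stack.n_frames} frames")
    f = stack.frames[:, roi.mask].mean(axis=1, dtype=np.float64)
    f0 = float(f[lo:hi].mean())
    if f0 <= 0:
        raise DataError(f"baseline fluorescence F0 = {f0} is not positive")
    return FluorescenceTrace(times=stack.frame_times_ms, dff=(f - f0) / f0,
                             f0=f0, baseline_window=baseline_window)


def detect_peaks(
    trace: FluorescenceTrace,
    k: float = 2.0,
    min_duration: int = 2,
    search_window: tuple[int, int] | None = None,
) -> list[PeakEvent]:
    """Maximal runs of >= min_duration consecutive frames with dff strictly
    above k * (baseline SD).  The baseline window needs >= 20 frames for a
    usable noise estimate."""
    lo, hi = trace.baseline_window
    if hi - lo < 20:
        raise DataError("baseline window must span at least 20 frames")
    noise_sd = float(np.std(trace.dff[lo:hi], ddof=1))
    thr = k * noise_sd

    dff = trace.dff
    n = len(dff)
    w_lo, w_hi = (0, n) if search_window is None else search_window
    w_lo, w_hi = max(0, w_lo), min(n, w_hi)
    above = np.zeros(n, dtype=bool)
    above[w_lo:w_hi] = dff[w_lo:w_hi] > thr   # strict inequality (tie-break rule)

    events: list[PeakEvent] = []
    edges = np.flatnonzero(np.diff(np.concatenate([[0], above.view(np.int8), [0]])))
    for start, stop in edges.reshape(-1, 2):
        if stop - start >= min_duration:
            peak = start + int(np.argmax(dff[start:stop]))
            events.append(PeakEvent(onset_frame=int(start), peak_frame=peak,
                                    amplitude=float(dff[peak]), end_frame=int(stop)))
    return events


def _exp_fit_fall_time(t_seg, y_seg, half_level):
    """Fit y = A exp(-(t - t0)/tau) to the repolarization segment and return
    (time at half_level, tau, A); raises on non-convergence."""
    t0 = t_seg[0]
    pos = y_seg > 0
    if pos.sum() < 3:
        raise RuntimeError("too few positive samples for exponential fit")
    # log-linear initialization
    slope, intercept = np.polyfit(t_seg[pos] - t0, np.log(y_seg[pos]), 1)
    tau0 = -1.0 / slope if slope < 0 else (t_seg[-1] - t0)
    a0 = float(np.exp(intercept))

    def model(t, a, tau):
        return a * np.exp(-(t - t0) / tau)

    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")   # singular covariance is fine; only popt is used
        popt, _ = curve_fit(model, t_seg, y_seg, p0=[a0, max(tau0, 1e-6)],
                            maxfev=200 * len(t_seg), xtol=1e-8, ftol=1e-8)
    a, tau = popt
    if tau <= 0 or a <= half_level:
        raise RuntimeError("degenerate exponential fit")
    sse_exp = float(np.sum((model(t_seg, *popt) - y_seg) ** 2))
    # model check: a straight line describing the fall better than the
    # exponential marks a degenerate (non-exponential) repolarization
    lin = np.polyval(np.polyfit(t_seg, y_seg, 1), t_seg)
    sse_lin = float(np.sum((lin - y_seg) ** 2))
    if sse_lin < sse_exp:
        raise RuntimeError("repolarization not exponential (linear model fits better)")
    t_fall = t0 + tau * np.log(a / half_level)
    if not t0 <= t_fall <= t_seg[-1] + (t_seg[-1] - t0):
        raise RuntimeError("fitted half-crossing outside the repolarization segment")
    return t_fall, float(tau), float(a)


def half_width(times, values, baseline: float | None = None) -> HalfWidthResult:
    """Half-width of the dominant peak of a uniformly sampled trace.

    The rising half-crossing is linearly interpolated between samples.  The
    falling half-crossing comes from a least-squares single-exponential fit to
    the repolarization (peak to first return below 10% of peak); if the fit
    fails or a straight line describes the fall better, the estimate falls
    back to sample interpolation and is flagged via ``method``.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if len(t) != len(y) or len(t) < 3:
        raise DataError("need equally long times/values with >= 3 samples")
    if baseline is None:
        baseline = float(np.median(y[: max(1, len(y) // 20)]))
    yy = y - baseline
    peak = int(np.argmax(yy))
    amp = yy[peak]
    if amp <= 0:
        raise DataError("trace has no positive peak above baseline")
    half = amp / 2.0

    # rising crossing: last sample below half before the peak
    below = np.flatnonzero(yy[:peak] <= half)
    if len(below):
        i = below[-1]
        t_rise = t[i] + (t[i + 1] - t[i]) * (half - yy[i]) / (yy[i + 1] - yy[i])
    else:
        t_rise = t[max(peak - 1, 0)] if peak else t[0]   # instantaneous rise

    # repolarization segment: peak -> first return below 10% of peak
    tail = yy[peak:]
    under = np.flatnonzero(tail < 0.1 * amp)
    end = peak + (under[0] + 1 if len(under) else len(tail))
    t_seg, y_seg = t[peak:end], tail[: end - peak]

    method = "exponential"
    tau = None
    try:
        t_fall, tau, _ = _exp_fit_fall_time(t_seg, y_seg, half)
    except (RuntimeError, ValueError, TypeError):
        method = "interpolated"
        t_fall = _interpolated_fall_time(t, yy, peak, amp, half)
    return HalfWidthResult(hw_ms=float(t_fall - t_rise), method=method,
                           t_rise=float(t_rise), t_fall=float(t_fall), tau_ms=tau)


def _interpolated_fall_time(t, yy, peak, amp, half):
    """Fallback falling half-crossing: a local least-squares line through the
    post-peak samples between 25% and 75% of the peak (exact for piecewise
    linear decays, noise-averaging for sampled ones); plain two-sample
    interpolation when fewer than three samples fall in that band."""
    tail = yy[peak:]
    below = np.flatnonzero(tail < 0.25 * amp)
    stop = below[0] + 1 if len(below) else len(tail)
    band = np.flatnonzero((tail[:stop] <= 0.75 * amp) & (tail[:stop] >= 0.25 * amp))
    if len(band) >= 3:
        tb, yb = t[peak + band], tail[band]
        m, b = np.polyfit(tb, yb, 1)
        if m < 0:
            t_cross = (half - b) / m
            # accept only if the crossing lies within (or just beyond) the band
            if tb[0] <= t_cross <= t[min(peak + stop, len(t) - 1)] + (tb[-1] - tb[0]):
                return t_cross
    under_half = np.flatnonzero(tail <= half)
    if not len(under_half):
        return t[-1]
    j = peak + under_half[0]
    return t[j - 1] + (t[j] - t[j - 1]) * (yy[j - 1] - half) / (yy[j - 1] - yy[j])


def labeling_specificity(image: np.ndarray, rois: list) -> float:
    """N_roi / N_im: the fraction of suprathreshold-bright pixels (strictly
    above mean + 2 SD of the whole image) lying inside any ROI."""
    img = np.asarray(image, dtype=float)
    thr = img.mean() + 2.0 * img.std()
    bright = img > thr
    n_im = int(bright.sum())
    if n_im == 0:
        raise UndefinedStatisticError("no pixels above mean + 2 SD")
    union = np.zeros(img.shape, dtype=bool)
    for r in rois:
        union |= r.mask if isinstance(r, ROI) else np.asarray(r, dtype=bool)
    return float((bright & union).sum() / n_im)


def normalize_to_8bit(image: np.ndarray) -> np.ndarray:
    """Linear rescale to uint8 clipping the bottom 0.5% of pixels to 0 and the
    top 0.5% to 255 (the detector gain/offset convention for confocal export)."""
    img = np.asarray(image, dtype=float)
    if img.size < 200:
        raise DataError("image must have at least 200 pixels")
    lo = np.quantile(img, 0.005)
    hi = np.quantile(img, 0.995)
    if hi <= lo:
        raise DegenerateRangeError("image intensity range is degenerate")
    out = np.clip((img - lo) / (hi - lo), 0.0, 1.0) * 255.0
    return np.rint(out).astype(np.uint8)


def classify_cells(
    stack: FrameStack,
    rois: list[ROI],
    stimulus_frame: int,
    baseline_window: tuple[int, int] = DEFAULT_BASELINE_WINDOW,
    search_frames: int = DEFAULT_SEARCH_FRAMES,
    k: float = 2.0,
    min_duration: int = 2,
) -> list[DetectionResult]:
    """Flag AP-capable cells: a cell fires if its post-stimulus dF/F0 trace
    contains a detected peak within ``search_frames`` frames of the stimulus."""
    if not rois:
        raise ConfigurationError("no ROIs supplied")
    if stimulus_frame < baseline_window[1]:
        raise ConfigurationError("stimulus frame must come after the baseline window")
    results = []
    window = (stimulus_frame, stimulus_frame + search_frames)
    for cid, roi in enumerate(rois):
        trace = compute_dff(stack, roi, baseline_window)
        lo, hi = baseline_window
        noise_sd = float(np.std(trace.dff[lo:hi], ddof=1))
        events = detect_peaks(trace, k=k, min_duration=min_duration, search_window=window)
        if events:
            best = max(events, key=lambda e: e.amplitude)
            seg_lo, seg_hi = stimulus_frame, min(window[1] + 50, len(trace.dff))
            hw = half_width(trace.times[seg_lo:seg_hi], trace.dff[seg_lo:seg_hi], baseline=0.0)
            results.append(DetectionResult(cell_id=cid, has_peak=True,
                                           peak_amplitude=best.amplitude,
                                           half_width_ms=hw.hw_ms, noise_sd=noise_sd,
                                           half_width_method=hw.method))
        else:
            results.append(DetectionResult(cell_id=cid, has_peak=False,
                                           peak_amplitude=None, half_width_ms=None,
                                           noise_sd=noise_sd))
    return results
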