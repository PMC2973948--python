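"""Synthetic VSD-imaging forward model.

Generates the two kinds of raw data the assay consumes:

* 1 kHz EM-CCD fluorescence movies of a cultured monolayer in which each
  cell's pixel intensity is a linear function of its membrane voltage
  (fractional gain ``DyeModel.gain`` per mV) riding on a baseline ``f0``,
  with Gaussian sensor noise of mean-proportional variance (the EM excess
  noise folded into ``shot_scale``) and optional mono-exponential bleaching;
* 8-bit confocal-like labeling images with a controllable fraction of
  specifically (inside-cell) versus non-specifically placed bright pixels,
  together with their ground-truth ROI masks.

The default dye gain of 5e-5 per mV is calibrated so a sustained +40 mV
voltage step produces a 0.2% dF/F0 plateau, the sensitivity measured for
extracellularly applied fast VSDs in voltage-clamp calibration experiments.

All randomness flows through an explicit per-call seed; rendering is
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import tifffile

from .errors import ConfigurationError, CoverageError, DomainError
from .membrane import VoltageTrace

__all__ = [
    "DyeModel",
    "LayoutCell",
    "CellLayout",
    "FrameStack",
    "render_movie",
    "synth_labeling_image",
    "ellipse_mask",
    "shot_scale_for_snr",
]

DEFAULT_GAIN_PER_MV = 5e-5   # 0.2% dF/F0 per +40 mV step


@dataclass
class DyeModel:
    """Voltage-to-fluorescence gain and EM-CCD noise model.

    gain: fractional dF/F0 per mV; f0: baseline cell fluorescence (counts);
    f0_bg: background fluorescence (counts); shot_scale: noise variance per
    unit mean (EM excess noise included); read_noise: additive RMS counts;
    bleach_tau: mono-exponential bleaching constant in ms (inf = no bleach,
    the LED scenario; finite for the lamp scenario).
    """

    gain: float = DEFAULT_GAIN_PER_MV
    f0: float = 2000.0
    f0_bg: float = 200.0
    shot_scale: float = 0.0
    read_noise: float = 0.0
    bleach_tau: float = np.inf

    def __post_init__(self):
        if self.gain < 0:
            raise DomainError("gain must be >= 0")
        if self.f0 <= 0:
            raise DomainError("f0 must be positive")
        if self.shot_scale < 0 or self.read_noise < 0:
            raise DomainError("noise parameters must be >= 0")

    def bleach(self, t_ms: np.ndarray) -> np.ndarray:
        if np.isinf(self.bleach_tau):
            return np.ones_like(np.asarray(t_ms, dtype=float))
        return np.exp(-np.asarray(t_ms, dtype=float) / self.bleach_tau)


@dataclass
class LayoutCell:
    """One cell in the synthetic field of view."""

    mask: np.ndarray                     # boolean pixel mask
    trace: VoltageTrace | None = None    # membrane voltage over the movie
    v_rest: float = -29.7                # mV, fluorescence baseline voltage
    ap_capable: bool = False


@dataclass
class CellLayout:
    """Image shape plus non-overlapping cell masks with assigned traces."""

    shape: tuple[int, int]
    cells: list[LayoutCell] = field(default_factory=list)

    def __post_init__(self):
        occupancy = np.zeros(self.shape, dtype=int)
        for i, c in enumerate(self.cells):
            if c.mask.shape != tuple(self.shape):
                raise ConfigurationError(f"cell {i} mask shape {c.mask.shape} != {self.shape}")
            occupancy += c.mask.astype(int)
        if np.any(occupancy > 1):
            raise ConfigurationError("cell masks overlap")

    @property
    def union_mask(self) -> np.ndarray:
        out = np.zeros(self.shape, dtype=bool)
        for c in self.cells:
            out |= c.mask
        return out


@dataclass
class FrameStack:
    """Time-ordered image frames: (n_frames, rows, cols) counts."""

    frames: np.ndarray
    frame_rate: float = 1000.0
    bit_depth: int = 14

    def __post_init__(self):
        if self.frame_rate <= 0:
            raise DomainError("frame_rate must be positive")
        if np.any(self.frames < 0):
            raise DomainError("frame counts must be >= 0")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_times_ms(self) -> np.ndarray:
        return np.arange(self.n_frames) * 1000.0 / self.frame_rate

    def save_tiff(self, path) -> None:
        tifffile.imwrite(path, self.frames.astype(np.float32))

    @classmethod
    def from_tiff(cls, path, frame_rate: float = 1000.0, bit_depth: int = 14) -> "FrameStack":
        arr = tifffile.imread(path)
        if arr.ndim == 2:
            arr = arr[None]
        return cls(frames=np.asarray(arr, dtype=np.float32),
                   frame_rate=frame_rate, bit_depth=bit_depth)


def ellipse_mask(shape: tuple[int, int], center: tuple[float, float],
                 r_row: float, r_col: float) -> np.ndarray:
    """Filled-ellipse boolean mask (row/col pixel coordinates, 0-based)."""
    from skimage.draw import ellipse

    rr, cc = ellipse(center[0], center[1], r_row, r_col, shape=shape)
    out = np.zeros(shape, dtype=bool)
    out[rr, cc] = True
    return out


def _frame_voltages(trace: VoltageTrace, n_frames: int, frame_interval_ms: float) -> np.ndarray:
    """Membrane voltage at each frame time (the dye responds in well under a
    frame, so each frame reports the instantaneous voltage)."""
    t_end = (n_frames - 1) * frame_interval_ms
    if trace.times[-1] + trace.dt < t_end - 1e-9:
        raise CoverageError(
            f"voltage trace covers {trace.times[-1]:.3f} ms but the movie needs "
            f"{t_end:.3f} ms"
        )
    frame_times = np.arange(n_frames) * frame_interval_ms
    return np.interp(frame_times, trace.times, trace.vm)


def render_movie(
    layout: CellLayout,
    dye: DyeModel,
    n_frames: int,
    frame_rate: float = 1000.0,
    seed: int | None = 0,
) -> FrameStack:
    """Render the noisy fluorescence movie of a layout.

    Pixel means: ``f0 * (1 + gain * (Vm(t) - v_rest)) * bleach(t)`` inside a
    cell, ``f0_bg * bleach(t)`` in the background.  Noise is Gaussian with
    variance ``shot_scale * mean + read_noise**2`` drawn independently per
    pixel per frame; with both noise terms zero the stack is exactly the
    noiseless forward model.  Deterministic given ``seed``.
    """
    if n_frames <= 0:
        raise ConfigurationError("n_frames must be positive")
    dt_f = 1000.0 / frame_rate
    t = np.arange(n_frames) * dt_f
    bleach = dye.bleach(t)

    mean = np.empty((n_frames, *layout.shape), dtype=np.float64)
    mean[:] = dye.f0_bg * bleach[:, None, None]
    for cell in layout.cells:
        if cell.trace is None:
            v = np.full(n_frames, cell.v_rest)
        else:
            v = _frame_voltages(cell.trace, n_frames, dt_f)
        cell_f = dye.f0 * (1.0 + dye.gain * (v - cell.v_rest)) * bleach
        mean[:, cell.mask] = cell_f[:, None]

    if dye.shot_scale == 0.0 and dye.read_noise == 0.0:
        frames = mean
    else:
        rng = np.random.default_rng(seed)
        sd = np.sqrt(dye.shot_scale * mean + dye.read_noise ** 2)
        frames = mean + rng.standard_normal(mean.shape) * sd
        np.clip(frames, 0.0, None, out=frames)
    return FrameStack(frames=frames.astype(np.float32), frame_rate=frame_rate)


def shot_scale_for_snr(
    peak_dff: float, snr: float, f0: float, roi_pixels: int
) -> float:
    """Shot-noise scale that sets the baseline SD of an ``roi_pixels``-average
    dF/F0 trace to ``peak_dff / snr`` (read noise assumed zero).

    Trace SD in dF/F0 units is sqrt(shot_scale * f0) / (f0 * sqrt(n_px)).
    """
    target_sd = peak_dff / snr
    return (target_sd * np.sqrt(roi_pixels) * f0) ** 2 / f0


def synth_labeling_image(
    layout: CellLayout,
    specificity: float,
    brightness_params: dict | None = None,
    seed: int | None = 0,
    n_bright: int | None = None,
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Synthesize an 8-bit confocal-like labeling image plus ground-truth masks.

    Each of ``n_bright`` suprathreshold pixels is placed inside a cell mask
    with probability ``specificity`` and uniformly over the whole image
    otherwise (debris / coating speckle), so with cell-area fraction ``a`` the
    expected in-cell fraction of bright pixels is ``specificity + (1 -
    specificity) * a``; keep the layout sparse (a of a few percent) for the
    statistic to read back the specificity parameter directly.

    brightness_params keys (defaults): bg_mean 30, bg_sd 8, cell_mean 45,
    cell_sd 8, bright_mean 230, bright_sd 8.

    Returns (uint8 image, list of boolean ROI masks).
    """
    if not 0.0 <= specificity <= 1.0:
        raise DomainError("specificity must lie in [0, 1]")
    p = {"bg_mean": 30.0, "bg_sd": 8.0, "cell_mean": 45.0, "cell_sd": 8.0,
         "bright_mean": 230.0, "bright_sd": 8.0}
    if brightness_params:
        p.update(brightness_params)
    rng = np.random.default_rng(seed)
    shape = layout.shape
    n_px = shape[0] * shape[1]
    if n_bright is None:
        n_bright = max(1, int(0.01 * n_px))

    img = p["bg_mean"] + p["bg_sd"] * rng.standard_normal(shape)
    union = layout.union_mask
    n_cell_px = int(union.sum())
    if n_cell_px == 0:
        raise ConfigurationError("layout has no cell pixels")
    img[union] = p["cell_mean"] + p["cell_sd"] * rng.standard_normal(n_cell_px)

    # distinct target pixels: collisions would silently merge bright pixels
    # and bias the measured in-cell fraction low
    cell_flat = np.flatnonzero(union.ravel())
    n_in = int(rng.binomial(n_bright, specificity))
    if n_in > n_cell_px:
        raise ConfigurationError("n_bright too large for the cell area at this specificity")
    targets = np.concatenate([
        rng.choice(cell_flat, size=n_in, replace=False),
        rng.choice(n_px, size=n_bright - n_in, replace=False),
    ])
    flat = img.ravel()
    flat[targets] = p["bright_mean"] + p["bright_sd"] * rng.standard_normal(len(targets))
    img = np.clip(flat.reshape(shape), 0, 255).astype(np.uint8)
    return img, [c.mask.copy() for c in layout.cells]
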