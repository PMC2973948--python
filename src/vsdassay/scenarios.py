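"""Canonical study conditions: ready-made parameter sets and end-to-end
reproduction scenarios tying simulation -> field model -> rendering -> analysis.

These encode the package's reference experiments:

* ``kinetics_sweep_experiment`` — simulate cells with graded Na-current
  kinetics, image them at 1 kHz, and regress the fluorescence half-width on
  the voltage half-width (optical readout fidelity).
* ``culture_detection_experiment`` — a 24-cell synthetic culture, half
  firing and half silent, pushed through the classification pipeline.
* ``cathode_distance_experiment`` — FEM of a fixed anode with the cathode
  stepped away from the cell (membrane polarization vs electrode placement).
* ``electrode_spread_experiment`` — the same 4-cell layout stimulated with
  closely spaced vs widely spaced poles (homogeneity of stimulation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .analysis import ROI, classify_cells, compute_dff, detect_peaks, half_width
from .field import (
    CultureGeometry,
    Electrode,
    StimulusPulse,
    membrane_polarization,
    solve_laplace,
    triangulate,
)
from .imaging import (
    CellLayout,
    DyeModel,
    LayoutCell,
    ellipse_mask,
    render_movie,
    shot_scale_for_snr,
)
from .membrane import KKinetics, NaKinetics, PassiveMembrane, StimProtocol, simulate_current_clamp

__all__ = [
    "default_membrane",
    "ap_kinetics",
    "ap_protocol",
    "simulate_ap",
    "kinetics_sweep_experiment",
    "build_culture_layout",
    "culture_detection_experiment",
    "cathode_distance_experiment",
    "electrode_spread_experiment",
]

#: tau_scale values spanning "mature" to strongly "immature" AP kinetics
#: (half-widths of roughly 3-20 ms under the default conductances).
DEFAULT_TAU_SCALES = tuple(np.geomspace(1.7, 11.5, 7).round(3))


def default_membrane() -> PassiveMembrane:
    """Passive properties of a 2-week differentiated cultured cell."""
    return PassiveMembrane(capacitance=18.3, input_resistance=3.3, resting_potential=-29.7)


def ap_kinetics(tau_scale: float = 1.0) -> tuple[NaKinetics, KKinetics]:
    """Sodium kinetics plus the host cell's delayed rectifier, both slowed by
    ``tau_scale`` (a uniform kinetic slowdown scales the whole AP time course,
    which is what distinguishes immature from mature spikes)."""
    return NaKinetics(tau_scale=tau_scale), KKinetics(tau_scale=tau_scale)


def ap_protocol(onset: float = 60.0, total_time: float = 250.0,
                dt: float = 0.025) -> StimProtocol:
    """The standard AP trigger: a 100 pA, 5 ms current step."""
    return StimProtocol(step_amplitude=100.0, onset=onset, duration=5.0,
                        total_time=total_time, dt=dt)


def simulate_ap(tau_scale: float = 1.0, proto: StimProtocol | None = None,
                mem: PassiveMembrane | None = None):
    """Current-clamp AP for one kinetic speed class; returns the VoltageTrace."""
    mem = mem or default_membrane()
    proto = proto or ap_protocol()
    na, kdr = ap_kinetics(tau_scale)
    return simulate_current_clamp(mem, na, proto, kdr=kdr)


@dataclass
class KineticsSweepResult:
    tau_scales: np.ndarray
    hw_voltage_ms: np.ndarray
    hw_fluorescence_ms: np.ndarray
    r_squared: float
    slope: float
    intercept: float


def _single_cell_layout(trace, v_rest: float, shape=(32, 32)):
    cell = LayoutCell(mask=ellipse_mask(shape, (16, 16), 7, 9),
                      trace=trace, v_rest=v_rest, ap_capable=True)
    roi = np.zeros(shape, dtype=bool)
    roi[14:19, 12:20] = True   # 40-pixel perisomatic rectangle inside the cell
    return CellLayout(shape=shape, cells=[cell]), ROI(roi)


def kinetics_sweep_experiment(
    tau_scales=DEFAULT_TAU_SCALES,
    snr: float = 10.0,
    seed: int = 0,
    frame_rate: float = 1000.0,
) -> KineticsSweepResult:
    """Half-width of the optical transient vs half-width of the underlying AP.

    For each kinetic speed class: simulate the AP, render a 1 kHz movie of a
    single cell with the baseline SD of the 40-pixel ROI trace set to
    peak dF/F0 / ``snr``, measure both half-widths with the exponential-fit
    repolarization procedure, and regress fluorescence HW on voltage HW.
    """
    mem = default_membrane()
    proto = ap_protocol()
    stim_frame = int(proto.onset * frame_rate / 1000.0)
    n_frames = int(proto.total_time * frame_rate / 1000.0)
    hw_v, hw_f = [], []
    rng = np.random.default_rng(seed)
    for ts in tau_scales:
        trace = simulate_ap(ts, proto, mem)
        hw_v.append(half_width(trace.times, trace.vm, baseline=mem.resting_potential).hw_ms)

        layout, roi = _single_cell_layout(trace, mem.resting_potential)
        peak_dff = DyeModel().gain * (trace.vm.max() - mem.resting_potential)
        dye = DyeModel(shot_scale=shot_scale_for_snr(peak_dff, snr, DyeModel().f0,
                                                     roi.n_pixels))
        stack = render_movie(layout, dye, n_frames=n_frames, frame_rate=frame_rate,
                             seed=int(rng.integers(0, 2**31 - 1)))
        ftrace = compute_dff(stack, roi, baseline_window=(0, 50))
        hw = half_width(ftrace.times[stim_frame:], ftrace.dff[stim_frame:], baseline=0.0)
        hw_f.append(hw.hw_ms)

    hw_v, hw_f = np.asarray(hw_v), np.asarray(hw_f)
    slope, intercept = np.polyfit(hw_v, hw_f, 1)
    pred = slope * hw_v + intercept
    ss_res = float(np.sum((hw_f - pred) ** 2))
    ss_tot = float(np.sum((hw_f - hw_f.mean()) ** 2))
    return KineticsSweepResult(
        tau_scales=np.asarray(tau_scales), hw_voltage_ms=hw_v, hw_fluorescence_ms=hw_f,
        r_squared=1.0 - ss_res / ss_tot, slope=float(slope), intercept=float(intercept),
    )


def build_culture_layout(
    n_firing: int = 12,
    n_silent: int = 12,
    shape=(128, 128),
    firing_tau_scales=(3.0, 4.5, 6.0),
    proto: StimProtocol | None = None,
    seed: int = 0,
) -> tuple[CellLayout, list[ROI], int, StimProtocol]:
    """A synthetic culture on a jittered grid: ``n_firing`` cells carry a
    simulated AP after the stimulus, the rest sit at rest.  Returns (layout,
    per-cell 20-pixel ROIs, stimulus frame, protocol)."""
    mem = default_membrane()
    proto = proto or ap_protocol(onset=60.0, total_time=200.0)
    n = n_firing + n_silent
    rng = np.random.default_rng(seed)

    cols = int(np.ceil(np.sqrt(n)))
    rows = int(np.ceil(n / cols))
    pitch_r, pitch_c = shape[0] // (rows + 1), shape[1] // (cols + 1)
    centers = [((r + 1) * pitch_r + int(rng.integers(-2, 3)),
                (c + 1) * pitch_c + int(rng.integers(-2, 3)))
               for r in range(rows) for c in range(cols)][:n]

    firing_flags = np.zeros(n, dtype=bool)
    firing_flags[rng.permutation(n)[:n_firing]] = True

    traces = {ts: simulate_ap(ts, proto, mem) for ts in firing_tau_scales}
    cells, rois = [], []
    for i, (cr, cc) in enumerate(centers):
        mask = ellipse_mask(shape, (cr, cc), 5, 5)
        if firing_flags[i]:
            ts = firing_tau_scales[i % len(firing_tau_scales)]
            cell = LayoutCell(mask=mask, trace=traces[ts],
                              v_rest=mem.resting_potential, ap_capable=True)
        else:
            cell = LayoutCell(mask=mask, trace=None,
                              v_rest=mem.resting_potential, ap_capable=False)
        cells.append(cell)
        roi = np.zeros(shape, dtype=bool)
        roi[cr - 2 : cr + 3, cc - 2 : cc + 2] = True   # 5x4 = 20 pixels
        rois.append(ROI(roi))
    layout = CellLayout(shape=shape, cells=cells)
    stim_frame = int(proto.onset)
    return layout, rois, stim_frame, proto


@dataclass
class CultureDetectionResult:
    results: list
    ap_capable: np.ndarray
    flagged: np.ndarray
    n_firing_flagged: int
    n_silent_flagged: int


def culture_detection_experiment(seed: int = 0, snr: float = 5.0,
                                 n_firing: int = 12, n_silent: int = 12,
                                 ) -> CultureDetectionResult:
    """Render the synthetic culture with firing-cell peak dF/F0 = ``snr`` x the
    20-pixel ROI baseline SD and classify every cell with the strict >2-sigma,
    >= 2-frame rule over a 100-frame post-stimulus window."""
    layout, rois, stim_frame, proto = build_culture_layout(
        n_firing=n_firing, n_silent=n_silent, seed=seed)
    # every firing cell's *observed* (frame-sampled) peak must clear snr x the
    # baseline SD, so calibrate against the weakest firing cell
    frame_times = np.arange(int(proto.total_time))
    peak_defl = min(
        np.interp(frame_times, c.trace.times, c.trace.vm).max() - c.v_rest
        for c in layout.cells if c.trace is not None
    )
    base = DyeModel()
    dye = DyeModel(shot_scale=shot_scale_for_snr(base.gain * peak_defl, snr, base.f0,
                                                 rois[0].n_pixels))
    n_frames = int(proto.total_time)
    stack = render_movie(layout, dye, n_frames=n_frames, seed=seed + 1)
    results = classify_cells(stack, rois, stimulus_frame=stim_frame)
    ap_capable = np.asarray([c.ap_capable for c in layout.cells])
    flagged = np.asarray([r.has_peak for r in results])
    return CultureDetectionResult(
        results=results, ap_capable=ap_capable, flagged=flagged,
        n_firing_flagged=int(np.sum(flagged & ap_capable)),
        n_silent_flagged=int(np.sum(flagged & ~ap_capable)),
    )


def _disc_polygon(center, radius, n=64):
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([center[0] + radius * np.cos(th),
                            center[1] + radius * np.sin(th)])


def cathode_distance_experiment(
    cathode_positions=(2.5, 5.0, 10.0),
    domain_radius: float = 15.0,
    cell_radius: float = 0.025,
    pulse: StimulusPulse | None = None,
    max_area: float = 1.0,
    reference: str = "bath",
):
    """Fixed anode at -2.5 mm, cell at the origin, cathode stepped away; 1 V,
    5 ms pulse.  Returns the per-position peak membrane polarization (mV,
    magnitude) of the cell."""
    pulse = pulse or StimulusPulse(amplitude=1.0, duration=5.0)
    mem = default_membrane()
    domain = _disc_polygon((0, 0), domain_radius, n=128)
    cell = _disc_polygon((0, 0), cell_radius, n=32)
    peaks = []
    for pos in cathode_positions:
        geom = CultureGeometry(
            domain=domain,
            electrodes=[Electrode((-2.5, 0.0), 0.025, +1), Electrode((pos, 0.0), 0.025, -1)],
            cells=[cell],
        )
        mesh = triangulate(geom, max_area=max_area)
        sol = solve_laplace(mesh, amplitude=pulse.amplitude)
        pol = membrane_polarization(sol, cell, mem, pulse, reference=reference)
        peaks.append(pol.peak_polarization)
    return np.asarray(peaks)


def electrode_spread_experiment(
    domain_radius: float = 15.0,
    far_cathode_x: float = 12.0,
    close_cathode_x: float = 3.0,
    pulse: StimulusPulse | None = None,
    max_area: float = 1.0,
    reference: str = "bath",
):
    """The same 4-cell patch stimulated with closely spaced poles (both
    flanking the patch) vs the cathode moved far away.  Returns a dict with
    per-cell peak polarizations and their coefficient of variation for both
    configurations."""
    pulse = pulse or StimulusPulse(amplitude=1.0, duration=5.0)
    mem = default_membrane()
    domain = _disc_polygon((0, 0), domain_radius, n=128)
    cells = [
        _disc_polygon((-1.0, 0.8), 0.35),
        _disc_polygon((0.6, 1.1), 0.30),
        _disc_polygon((-0.3, -1.0), 0.40),
        _disc_polygon((1.2, -0.6), 0.30),
    ]
    out = {}
    for name, cathode_x in (("close", close_cathode_x), ("far", far_cathode_x)):
        geom = CultureGeometry(
            domain=domain,
            electrodes=[Electrode((-3.0, 0.0), 0.025, +1),
                        Electrode((cathode_x, 0.0), 0.025, -1)],
            cells=cells,
        )
        mesh = triangulate(geom, max_area=max_area)
        sol = solve_laplace(mesh, amplitude=pulse.amplitude)
        peaks = np.asarray([
            membrane_polarization(sol, c, mem, pulse, reference=reference).peak_polarization
            for c in cells
        ])
        out[name] = {"peaks_mv": peaks, "cv": float(peaks.std(ddof=0) / peaks.mean())}
    return out
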