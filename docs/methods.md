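# Methods

This note documents the models behind `vsdassay`, the parameter choices that
matter, and what the synthetic experiments do and do not establish.

## Membrane model

The simulated cell is the passive equivalent circuit measured in immature
cultured cells: C_m = 18.3 pF, R_in = 3.3 GΩ (membrane time constant
τ_m = 60.4 ms) and a depolarized resting potential V_rest = −29.7 mV. All
excitable currents are injected on top of it, mirroring a dynamic-clamp
experiment in a cell with no native Na⁺ current:

C_m dV/dt = −(V − V_rest)/R_in − ḡ_Na m³h (V − V_Na) − ḡ_K n⁴ (V − E_K) + I_inj + I_hold

**Rate functions.** The α/β rate functions for m, h and n are the classical
squid-axon forms evaluated at V − v_shift. The measured resting potential of
these cells is far above the classical operating range, so the default shift
v_shift = +35.3 mV maps V_rest = −29.7 mV onto the classical −65 mV resting
point; threshold then sits near −20 mV, safely above rest. (Aligning
threshold below the resting potential would make rest unstable.) All
coefficients are exposed through `rate_params` for substitution.

**Fast vs slow kinetics.** A single factor `tau_scale ≥ 1` divides every α
and β, leaving steady-state curves m_∞, h_∞, n_∞ untouched while stretching
all time constants uniformly. This isolates kinetic speed — the property
that distinguishes mature from immature action potentials — from every other
determinant of the waveform. The reference AP scenarios apply the same
factor to the delayed rectifier so that the entire AP time course scales;
half-width is then monotone in `tau_scale` by construction and spans roughly
3–20 ms over `tau_scale` ∈ [1.7, 11.5] at the default conductances.

**Conductances.** Defaults are classical channel densities scaled to the
cell's capacitance: ḡ_Na = 2.2 µS and ḡ_K = 0.66 µS (120 and 36 mS/cm² at
1 µF/cm²). The delayed rectifier is off by default in
`simulate_current_clamp` — the dynamic clamp injects only I_Na — but the AP
reference scenarios enable it: with leak alone (0.3 nS), repolarization
would be limited by τ_m = 60 ms and every AP would be tens of ms wide
regardless of kinetics; real host cells repolarize through native outward
conductances. E_K = −41.7 mV is the classical −77 mV carried through the
voltage shift.

**Holding current.** `I_hold` is the constant current that balances the
injected conductances at V_rest, making the *measured* resting potential an
exact equilibrium of the model (experimentally, V_rest is observed with all
native currents present). Without it, the Na window current alone would
shift rest by several mV at gigaohm input resistance.

**Integration.** Gates advance by exponential (Rush–Larsen) updates; the
voltage advances by an exponential update with conductances frozen over the
step. At full sodium conductance the voltage time constant dips to ~8 µs,
below the 25 µs step of the 40 kHz command loop, so a forward-Euler voltage
update would be unstable; the exponential update is unconditionally stable,
exact for the passive cell (the ḡ_Na = 0 trace matches the analytic RC
response to machine precision), and converged at dt = 0.025 ms (halving dt
changes AP half-width by <0.1%). Convergence for AP traces is asserted on
half-width rather than max-norm: any finite dt shifts a ~2000 mV/ms upstroke
by more than 0.1 mV in max-norm, so a max-norm criterion is only meaningful
for subthreshold responses.

## Extracellular field and membrane coupling

The bath is purely resistive, so the potential obeys ∇·(σ∇φ) = 0 with
φ = ±A/2 on the two electrode discs and zero normal flux on the coverslip
edge. Under Dirichlet data the solution is independent of σ; the default
1.5 S/m (physiological saline) is retained for future current-controlled
boundary conditions. Electrodes are regularized as discs of 25 µm radius
(the uncoated-tip area of a bipolar tungsten electrode) to avoid singular
point sources.

**Meshing.** The domain is triangulated by Delaunay refinement over a point
set built from boundary samples, electrode rings, cell outlines (≥64 samples
each), and a deterministic low-discrepancy interior seeding whose density
scales with `domain_area / max_area`; triangles whose area exceeds a size
field (fine near electrodes, `max_area` elsewhere) are split at their
centroids until conforming. Every interior element satisfies
area ≤ max_area, and requesting a finer mesh strictly increases the node
count.

**Accuracy.** Linear elements reproduce the parallel-plate solution exactly
(midline potential 0 to 1e−9 V), and a two-disc bipole in a large disc
matches the closed form c·ln(r₋/r₊) + const within 2% at all nodes farther
than five electrode radii from each pole and from the boundary. The
remaining discrepancy is dominated by the insulating-boundary images that
the free-space closed form omits, which is why the oracle geometry keeps the
pole separation small relative to the domain (1 mm poles in a 50 mm dish).

**Membrane polarization.** Cells do not perturb the field (one-way
coupling). Each cell outline is discretized into ≥64 equal-arc segments;
segment s obeys τ d(ΔV_m)/dt + ΔV_m = −(φ_e(s) − φ_ref)·1000 mV during the
pulse and relaxes with τ = R_in·C_m afterwards, solved in closed form. Two
references are supported:

- `perimeter` (default): φ_ref is the perimeter mean — the compact closed
  cell, driven only by the potential *variation* across its outline, with
  exactly zero net drive (a uniform field depolarizes one side exactly as
  much as it hyperpolarizes the other).
- `bath`: φ_ref = 0 — a cell whose processes extend beyond the stimulated
  region, pinning its interior to the bath potential; the local membrane
  then feels the full extracellular offset. This is the long-fiber limit of
  the cable description of extracellular stimulation.

The electrode-placement experiments use the `bath` reference and compare
peak polarization magnitude (as an amplitude-based optical readout would).
The distinction is physical, not cosmetic: for a compact cell the drive is
gradient-limited and *decreases* as the cathode recedes at fixed amplitude,
whereas a bath-referenced cell parked near one pole of a widely separated
pair rides the near-pole potential plateau — the configuration that
experimentally produces larger and more spatially homogeneous responses.
Both behaviours are available and tested.

`min_suprathreshold_voltage` exploits the linearity of both the field and
the membrane response in the applied amplitude: a single unit-amplitude
solve plus a bisection to 0.01 V over (0, 10] V.

## Imaging forward model

Cell pixels have mean f₀·(1 + g·(V_m(t) − V_rest))·B(t), background pixels
f₀_bg·B(t), with B(t) mono-exponential bleaching (off by default — the LED
illumination scenario). V_m is sampled at frame times; the dye responds in
well under a frame. The default gain g = 5×10⁻⁵/mV is calibrated so a
+40 mV step yields ΔF/F₀ = 0.2%, the sensitivity of extracellularly applied
fast VSDs under low-intensity LED excitation. Sensor noise is Gaussian with
variance `shot_scale`·mean + `read_noise`², a standard approximation of an
EM-CCD at moderate intensities in which `shot_scale` absorbs the EM excess
noise factor; no explicit gain-register cascade, PSF or photodamage is
modelled. Frames are kept in floating point (a 14-bit quantization step
would be invisible at the default f₀ = 2000 counts but would break exactness
of the calibration identities). All randomness flows through one explicit
seed per call.

`shot_scale_for_snr` inverts the noise model: given an ROI of n pixels it
returns the `shot_scale` that puts the baseline SD of the ROI-averaged
ΔF/F₀ trace at `peak_dff / snr`, which is how the reference experiments pin
their signal-to-noise conditions.

**Labeling images.** `synth_labeling_image` places a fixed number of bright
pixels (default 1% of the image): each lands on a uniformly chosen cell
pixel with probability `specificity`, otherwise uniformly anywhere (debris
and coating speckle). Target pixels are drawn without replacement —
collisions would silently merge bright pixels and bias the statistic low.
The expected measured statistic is s + (1−s)·a where a is the cell-area
fraction; the default layout keeps a ≈ 2%, so the estimator reads the
generator parameter back within ±0.02 and degrades gracefully to the chance
level a at s = 0.

## Analysis pipeline

ΔF/F₀ uses a 50-frame pre-stimulus baseline by default and is scale-free by
construction. Peak detection estimates the noise SD from the baseline
window (sample SD, ddof = 1) and defines an event as a maximal run of at
least 2 consecutive frames *strictly* above 2× that SD; classification
restricts the search to a 100-frame post-stimulus window. Thresholds,
window lengths and the run-length minimum are configurable; the strict
inequality is the declared tie-break. Note that this rule's intrinsic
false-positive rate on pure noise is ≈5% per 100-frame trace (two
consecutive >2σ excursions), so a plate of silent cells will occasionally
contribute a spurious flag — matching the experimental observation that
no-peak classification is less specific than peak detection.

Half-width: the rising half-crossing is linearly interpolated between
samples; the falling crossing comes from an unweighted least-squares
single-exponential fit to the repolarization segment (peak to first return
below 10% of peak), initialized from the log-linear slope. The fit is
rejected — and the estimate falls back to a sample-interpolated crossing,
flagged in the result — when it fails to converge, yields non-physical
parameters, places the crossing outside the segment, or when a straight
line fits the segment better than the exponential (a degenerate,
non-exponential decay such as a linear ramp). The fallback interpolates on
a local least-squares line through the samples between 25% and 75% of peak,
which is exact for piecewise-linear waveforms and noise-averaging for
sampled ones.

The labeling-specificity statistic thresholds the whole image (ROI pixels
included) at mean + 2 SD and reports the fraction of suprathreshold pixels
inside any ROI. `normalize_to_8bit` reproduces the confocal export
convention: linear rescale clipping the bottom and top 0.5% of pixels to 0
and 255.

## Reference experiments and their scope

- **Kinetics sweep** (7 cells, `tau_scale` 1.7–11.5, HW ≈ 3–20 ms, 1 kHz,
  40-pixel ROI, peak SNR 10): regression of optical on electrical
  half-width attains r² ≈ 0.98. At this SNR the r² estimate itself is
  stochastic with roughly ±0.02 spread across noise realizations; the
  residual variance comes almost entirely from the half-level's dependence
  on the noisy peak sample, which the prescribed estimator cannot average
  away.
- **Culture detection** (24 cells, 12 firing with immature APs — these
  cultures' AP-capable cells are slow — 12 silent, firing-cell sampled peak
  ΔF/F₀ = 5× baseline SD): all 12 firing cells are flagged; silent cells
  contribute 0–2 chance-level false positives per run, as the 2σ rule's own
  statistics dictate. Noise is calibrated against the *weakest* firing
  cell's frame-sampled peak so the stated SNR condition holds for every
  cell.
- **Electrode placement**: the cathode-distance sweep (anode −2.5 mm, 1 V,
  5 ms, cathode 2.5/5/10 mm) yields strictly increasing peak polarization,
  and the far-electrode configuration stimulates a 4-cell patch with a
  lower coefficient of variation than the flanking configuration.

Problem sizes (frame counts, image sizes, mesh densities, trace counts) are
chosen so each reference experiment completes in seconds on a single core
while keeping every statistical check inside its stated tolerance.

## What the synthetic data does not capture

The generator emulates voltage-to-fluorescence transduction and sensor
noise, not optics: no point-spread function, focus drift, illumination
inhomogeneity, dye internalization, photodamage, or movement artifacts.
Cells are disjoint filled shapes with uniform gain; real labeling varies
across membrane area and includes out-of-focus fluorescence. Passing the
suite therefore demonstrates correctness of the modelling and analysis
chain under the stated noise model, not robustness to every nuisance a real
rig produces. The FEM model likewise ignores electrode–electrolyte
interface impedance and 3D current spread, and treats threshold as a fixed
depolarization criterion rather than an excitable-membrane response.
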