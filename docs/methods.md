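# Methods

This note documents the models, estimators, defaults and numerical choices
behind `pvsflow`, and what the synthetic validation does and does not
establish about real recordings.

## The measurement problem

CSF in the perivascular spaces of pial arteries is seeded with 1 µm
fluorescent microspheres and imaged at ~30 Hz through a cranial window,
with ECG (1 kHz) and respiration (250 Hz) recorded simultaneously. The
analysis must (a) remove rigid frame motion, (b) convert microsphere
movies into per-frame velocity measurements while excluding stagnant
material, (c) reduce the measurements to time-averaged fields and summary
speeds, (d) relate the scalar flow-intensity series v_rms(t) to the
cardiac and respiratory cycles, (e) extract arterial wall kinematics from
transverse line scans, and (f) place the flow in dimensionless terms
(Re, Pe). Animal recordings are not distributed, so a generator produces
every input with known generating parameters, and validation is parameter
recovery against that stored truth.

## Synthetic data: what it emulates

**Flow movies.** The PVS is modeled as a 2-D channel of width *w* (default
45 µm, matching the measured average PVS width L = 44 µm used in the
scaling relations) with a no-slip parabolic profile
v(y, t) = 6 U (y/w)(1 − y/w) · m(t), where U is the target spatiotemporal
mean speed (default 18.7 µm/s). A 2-D parabola is the minimal structure
consistent with the observed nearly parabolic cross-channel profiles;
channel depth is ignored. The cardiac modulation m(φ) is built from
cos^2p bumps of the cardiac phase: unit time average, prescribed
(max−min)/max depth (default 0.99), peak lagging the R wave by a set delay
(default 34.5 ms). An optional backflow fraction carves a narrow negative
excursion into diastole occupying a set fraction of each cycle; the
waveform is rescaled to keep a unit mean. Inter-beat intervals jitter with
SD 4 ms so that 30 Hz sampling sweeps the cardiac phase instead of
aliasing onto six fixed phases. Particles take Brownian steps of variance
2DΔt per axis with D defaulting to the Stokes–Einstein value for 1 µm
spheres at 36.8 °C (6.55e-13 m²/s), so the synthetic Péclet number is
physiologic. A stuck fraction (default 5%) sits frozen within 1 µm of the
walls. Rendering uses isotropic Gaussian spots (σ = 1 px — no optics
model), Poisson photon noise on a uniform background, and an optional
recorded rigid frame jitter. The vessel channel is a textured artery band
drawn on a canvas larger than the frame, from which each jittered frame is
cropped — as with a real camera, jitter brings new scene content in at the
edges rather than a false border. The stored ground truth carries the
*advective* velocity of every particle in every frame; Brownian motion is
measurement physics, not signal, and recovery tests account for it.

**Wall line scans.** Each scan line is a smoothed top-hat (logistic edges,
sharpness 1.5 px) whose edges sit at ± d(t)/2. The default
"fast-rise/slow-fall" diameter waveform is constructed in the velocity
domain: a narrow cos¹⁶ systolic expansion pulse centered at the wall lag
minus a broad cos⁴ recovery lobe in antiphase, scaled to zero cycle mean
and integrated analytically. Because cos^2p contains harmonics only up to
order p, the diameter waveform is band-limited to 8 harmonics and the
order-8 Fourier fit used downstream can represent it without truncation
bias — the recovery test then probes the estimator, not an arbitrary
basis mismatch. `WallScenario.for_peak_wall_velocity` inverts the scaling
so a scenario can be pinned to a target peak wall velocity (e.g.
21.2 µm/s at a 34.5 ms lag).

**Physiology.** ECG is a train of 4 ms Gaussian R spikes on baseline
noise; respiration is a smooth periodic bump train. Peak times are snapped
to the sample grids so noise-free detection is exact by construction.

**Geometry.** An elliptical artery is flanked by two non-overlapping
rectangular PVS lobes whose pixel count equals the requested area ratio
times the rasterized artery area (exact to ±1 px); tracer positions are
sampled uniformly over the lobes. The ground truth includes an ROI equal
to artery ∪ PVS: the manual region-of-interest choice of the original
procedure, made reproducible. Without it, the 1 px inflation rim of the
track mask would add a systematic ~10–15% to the recovered ratio; a tight
ROI removes the rim exactly as a human-drawn region would.

**What the generator does not emulate:** optics (scattering, depth
attenuation, anisotropic PSF), vessel branching and curvature, spatially
varying backgrounds, particle aggregation dynamics, drift in physiological
rates, or motion blur. Passing recovery tests therefore demonstrates
estimator correctness under the stated statistical structure, not
robustness to every artifact of in-vivo imaging.

## Estimators and defaults

**Registration.** Shifts come from upsampled cross-correlation
(upsample 50, i.e. 0.02 px grid); the contract is ≤ 0.2 px error on clean
shifted content. The reference is built in two passes: the temporal mean
of the frames best correlated with the raw mean, then the mean of the
pass-1-registered frames; the refinement pass crops the shift-contaminated
border first, because the zero-filled edge strips otherwise anchor the
correlation at zero shift. Outlier shifts (> 3 px from a running median,
or non-finite) are repaired by linear interpolation, clamped at the ends;
a series with no valid frames raises the exclusion used for unregistrable
recordings. Translated frames are resampled with linear interpolation
onto a zero-padded canvas; pad amounts round up to 15 px (two analysis
boxes) so the binning grid anchored at pixel (0, 0) stays in registry
with the original coordinates.

**Tracking.** Detection: local maxima above a threshold (pipeline default:
median + 10 scaled MADs of the first frame), ≥ 3 px apart, refined by an
intensity-weighted centroid of the above-threshold signal in a 7×7 window.
Linking: greedy assignment in order of increasing displacement within a
5 px gate — equivalent to mutual-best matching, deterministic tie-breaks.
`link_tracks` defaults to matching around the last position; the pipeline
enables the predictive option (constant-velocity extrapolation), which
prevents identity swaps when systolic displacements approach the
inter-particle spacing. No gap closing: a missed detection terminates the
track, keeping every velocity strictly frame-adjacent. Velocities are
central differences (one-sided at track ends) scaled to µm/s. The
stagnant mask thresholds the time-averaged microsphere channel at its
99.5th percentile; measurements inside it are discarded, and tracks with
mean speed (path length per frame tracked) below 2 µm/s are dropped.

**Flow statistics.** The velocity field averages measurements in
7.5 × 7.5 px boxes anchored at pixel (0, 0); boxes with fewer than 20
measurements are invalid. U is the equal-weight mean over valid boxes of
|time-averaged velocity|. The equal-weight box mean is exact in
expectation when boxes tile the channel evenly but over-weights the slow
no-slip region when walls cut boxes partially (a −8% continuum bias for
this geometry); the generator's default layout places the walls on box
boundaries so the recovery test isolates the estimator chain from that
discretization artifact, which remains present — and documented — for
arbitrary geometries. v_rms(t) is the RMS of all speeds in a frame (NaN
for empty frames, never zero). Downstream components are u · û_avg with
û_avg the unit vector of the box's time-averaged velocity; zeros count as
forward flow. Recordings with fewer than 80 valid non-stagnant boxes are
excluded. For condition-to-condition speed changes, boxes with mean speed
below the same 2 µm/s stagnation constant are additionally excluded.

**Cardiac/respiratory conditioning.** R peaks: local maxima above
mean + 2 SD with a 50 ms refractory period; respiration reuses the
detector with smoothing and a 250 ms refractory period. Phase is elapsed
fraction of the local inter-peak interval. The conditional average uses
25 cardiac × 10 respiratory bins; empty bins stay NaN. Marginals average
the 2-D surface uniformly over the other cycle's defined bins: with ~99%
cardiac modulation, a direct count-weighted phase average lets cardiac
leakage inflate the respiratory marginal by tens of points on records of
realistic length (the effect measured 25–53% against a 22% truth on
120 s), because the cardiac phase is never sampled perfectly evenly
within a respiratory bin. Uniform marginalization removes that first-order
leakage (recovering 20.7–21.5%); the count-weighted marginals remain
available as `weighted_marginals()`. Modulation depth is
100 × (max − min)/max of the marginal — chosen because a ~99% cardiac
depth coexists with near-zero v_rms between beats — with
(max − min)/mean as a switchable alternative. Delay distributions pair
each reference peak with the *next* v_rms peak (local maxima with
prominence ≥ 25% of the IQR and spacing ≥ half the median R-R interval),
in 10 ms bins, normalized to density. Spectra are plain periodograms.

**Wall kinematics.** The edge threshold is the intensity of the
time-averaged profile at its steepest gradient (middle of the plateau for
piecewise-linear edges). Each line is cubic-interpolated onto a 10× finer
grid; the outermost up/down threshold crossings bound the artery, and
failures are interpolated across gaps of at most 5 samples. Δd subtracts
a centered moving average spanning two median R-R intervals (edges
flagged). The phase waveform uses 50 bins, normalized by the record-mean
diameter (not per-cycle means). The Fourier order is fixed at 8 — the
sharp systolic rise needs more than 4 harmonics — and the analytic
derivative is evaluated on a 1000-point phase grid (0.2 ms resolution at
5 Hz), with the peak taken on that grid.

**Scaling.** D = kT/(6πηr), Re = UL/ν, Pe = UL/D with water-at-36.8 °C
constants (ν = 0.697e-6 m²/s, η = 6.93e-4 kg/m/s), T = 310 K,
r = 0.5 µm, and L = 44 µm; k is a fixed constant. The identity
Pe·D = Re·ν = U·L holds to floating point by construction and is tested.

## Validation problem sizes

Recovery tests run on a 30 s, 100-particle movie at 30 Hz (mean-speed
recovery within 10%; the measured bias is under 4%), 45 s of 600 Hz line
scans (peak wall velocity within 5%, delay within one 4 ms phase bin),
120 s of 30 Hz v_rms (both modulation depths within 5 points), and 2000
sampled tracer positions per geometry (area ratios within 0.05). These
sizes keep the full suite to a couple of minutes on one CPU while leaving
each statistical check comfortably inside its tolerance.

## Known limitations

- Identity purity degrades when particles approach within the detector's
  resolution (~6 px for the centroid window): merged detections cannot be
  attributed to either particle, and such encounters are excluded from the
  identity guarantee rather than solved.
- The wall-velocity peak estimate inherits a small low bias (~1.5%) from
  fitting binned means attributed to bin centers; it is well inside the
  5% recovery tolerance and left uncorrected for fidelity to the binned
  procedure.
- The equal-weight box mean of U is geometry-sensitive near walls (see
  above); on arbitrary registered geometries its discretization bias is
  part of the measurement, as it is in the original procedure.
- Between-animal aggregation and hypothesis testing are out of scope; all
  comparisons here are within-run or between synthetic condition pairs.
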