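# pvsflow

Quantification of cerebrospinal-fluid (CSF) flow in the perivascular spaces
(PVSs) that surround brain surface arteries, from two-photon particle-imaging
movies synchronized with physiological signals.

CSF moves through PVSs in a pulsatile fashion, driven by the motion of the
arterial wall over each cardiac cycle ("perivascular pumping"). Measuring
that flow means tracking fluorescent microspheres frame by frame, relating
every velocity sample to the phase of the cardiac and respiratory cycles,
and reading the arterial wall's own motion from high-rate line scans. This
package implements that analysis chain as a library, plus a ground-truthed
synthetic-data generator so every stage can be validated without animal
recordings:

- **registration** — rigid subpixel alignment of image time series
  (upsampled cross-correlation, automated outlier repair, zero-padded
  resampling);
- **tracking** — subpixel microsphere detection, greedy mutual-nearest or
  predictive linking, per-frame velocities, stagnant-particle masking, and
  a ~2 µm/s slow-track filter;
- **flow_stats** — 7.5 px binned time-averaged velocity fields (≥ 20
  measurements per bin), mean flow speed *U*, the spatial-RMS series
  v_rms(t), wall-distance speed profiles, signed downstream components
  **u**·û_avg and backflow percentages, and the ≥ 80 non-stagnant-bin
  quality rule;
- **physio_sync** — ECG R-peak and respiration peak detection, cardiac /
  respiratory phase assignment, two-cycle conditional averaging of v_rms,
  modulation depths, peak-delay distributions, power spectra;
- **wall_kinematics** — artery diameter from line-scan kymographs by cubic
  interpolation and threshold crossing, two-cardiac-cycle detrending,
  phase-binned Δd/d waveforms, order-8 Fourier fits and the analytic wall
  velocity with its delay after the R wave;
- **geometry_scaling** — PVS/artery area ratios (including the 3×3
  track-inflation mask procedure), PVS width, and the transport numbers
  D = kT/6πηr, Re = UL/ν, Pe = UL/D;
- **synthetic** — movies of microspheres advected by a pulsatile parabolic
  channel flow v(y,t) = 6U(y/w)(1−y/w)·m(t) with Brownian jitter, stuck
  particles, frame jitter and photon noise; ECG/respiration traces; artery
  line scans with a fast-rise/slow-fall diameter waveform; and PVS/artery
  mask geometries — each with its generating parameters stored as ground
  truth;
- **pipeline** — end-to-end orchestration with JSON-serializable
  configuration, exclusion rules, and normal-vs-hypertension-analogue
  condition comparison.

## Worked example

Analyze a synthetic 30 s recording generated at a mean flow speed of
18.7 µm/s (the scale reported for murine pial PVSs):

```sh
$ pvsflow run --seed 0
{
  "excluded": false,
  "exclusion_rule": null,
  "mean_speed_um_s": 18.615779984664663,
  "true_mean_speed_um_s": 19.26226068446384,
  "backflow_percent": 17.24137931034483,
  "n_valid_bins": 162
}
```

The pipeline registered the movie, tracked the microspheres, filtered
stagnant material, and recovered a mean flow speed of 18.6 µm/s against the
movie's realized ground truth of 19.3 µm/s (−3.4%). 162 bins carried at
least 20 measurements, clearing the 80-bin quality rule, and 17% of the
downstream velocity components were negative — instantaneous backflow from
Brownian motion and measurement noise, present even with no net reverse
flow in the generator.

The same from Python, with the transport numbers:

```python
from pvsflow import RunConfig, run_synthetic_experiment
from pvsflow.synthetic import FlowScenario

result, truth = run_synthetic_experiment(RunConfig(), FlowScenario(seed=0))
print(result.summary.mean_speed)   # 18.615779984664663  (µm/s)
print(result.numbers.Re)           # 0.0011751...  -> flow is strictly laminar
print(result.numbers.Pe)           # 1250.5...     -> advection dominates diffusion
```

Morphometry via the track-inflation procedure (round positions, inflate to
3×3 px, subtract artery overlap, count within an ROI):

```sh
$ pvsflow geometry --ratio 1.4 --seed 1
{
  "true_ratio": 1.3999066728884741,
  "recovered_ratio": 1.3971068595426972
}
```

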