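"""Ground-truthed synthetic data emulating perivascular CSF flow recordings.

Everything the downstream analysis consumes can be generated here with a
known answer attached: two-channel fluorescence movies of microspheres
advected by pulsatile, nearly parabolic channel flow; ECG/respiration traces
with stored peak times; line-scan kymographs of an artery whose diameter
follows a fast-rise/slow-fall cardiac waveform; and artery/PVS mask
geometries with a prescribed area ratio.

All randomness flows through explicit integer seeds; identical scenario +
seed gives bit-identical output.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from math import comb

import numpy as np
from scipy import ndimage

from .io import ImageStack
from .physio_sync import PhysioRecord

#: µm² per m²
_M2_TO_UM2 = 1e12


# ---------------------------------------------------------------------------
# periodic waveform primitives
# ---------------------------------------------------------------------------

def periodic_bump(phase: np.ndarray, center: float, power: int) -> np.ndarray:
    """cos^(2p) bump: smooth, periodic, peak 1 at ``center``, zero at the antiphase.

    Band-limited by construction — cos^(2p) contains harmonics only up to
    order p, so waveforms built from these bumps are exactly representable by
    a Fourier series of that order.
    """
    return np.cos(np.pi * (np.asarray(phase, float) - center)) ** (2 * power)


def periodic_bump_mean(power: int) -> float:
    """Cycle average of cos^(2p): C(2p, p)/4^p."""
    return comb(2 * power, power) / 4.0 ** power


def cardiac_modulation_waveform(depth: float, peak_phase: float = 0.0,
                                pulse_power: int = 3) -> "callable":
    """Unit-mean periodic modulation factor with prescribed (max−min)/max depth.

    Returns ``m(phase)`` with time average exactly 1, minimum ``m0`` and
    ``(max − min)/max == depth``. Used both for the flow-speed modulation of
    the particle movie and for direct v_rms synthesis.
    """
    if not 0.0 <= depth < 1.0:
        raise ValueError("modulation depth must be in [0, 1)")
    hm = periodic_bump_mean(pulse_power)
    r = 1.0 / hm                      # max/mean of the bump
    m0 = (1.0 - depth) * r / (depth + (1.0 - depth) * r)

    def m(phase):
        return m0 + (1.0 - m0) / hm * periodic_bump(phase, peak_phase, pulse_power)

    return m


def _solve_backflow_lobe(base, peak_phase: float, target_fraction: float,
                         lobe_power: int = 12) -> float:
    """Amplitude of a diastolic negative lobe giving the target negative-phase fraction."""
    grid = np.linspace(0.0, 1.0, 8192, endpoint=False)
    base_vals = base(grid)
    lobe = periodic_bump(grid, peak_phase + 0.5, lobe_power)
    lo, hi = 0.0, 10.0 * base_vals.max()
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if np.mean(base_vals - mid * lobe < 0) < target_fraction:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def flow_modulation(depth: float, peak_phase: float = 0.0,
                    backflow_fraction: float = 0.0,
                    pulse_power: int = 3, lobe_power: int = 12) -> "callable":
    """Flow-speed modulation m(phase): unit mean, set depth, optional backflow.

    With ``backflow_fraction`` > 0 a narrow negative excursion occupying that
    fraction of each cycle is carved into diastole, then the waveform is
    rescaled back to unit mean (rescaling preserves both the sign set and the
    depth ratio).
    """
    base = cardiac_modulation_waveform(depth, peak_phase, pulse_power)
    if backflow_fraction <= 0:
        return base
    amp = _solve_backflow_lobe(base, peak_phase, backflow_fraction, lobe_power)
    grid = np.linspace(0.0, 1.0, 8192, endpoint=False)
    scale = 1.0 / np.mean(base(grid) - amp * periodic_bump(grid, peak_phase + 0.5, lobe_power))

    def m(phase):
        return scale * (base(phase) - amp * periodic_bump(phase, peak_phase + 0.5, lobe_power))

    return m


def _peak_times(frequency: float, duration: float, rng: np.random.Generator | None,
                interval_jitter: float) -> np.ndarray:
    """Strictly increasing beat times covering [0, duration] with optional jitter."""
    n = int(np.ceil(duration * frequency)) + 2
    intervals = np.full(n, 1.0 / frequency)
    if interval_jitter > 0 and rng is not None:
        intervals = intervals + rng.normal(0.0, interval_jitter, n)
        intervals = np.clip(intervals, 0.2 / frequency, None)
    # start half a period in so the first peak is detectable (not at sample 0)
    times = 0.5 / frequency + np.concatenate([[0.0], np.cumsum(intervals)])
    return times[times <= duration + 1.0 / frequency]


# ---------------------------------------------------------------------------
# ground truth container
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Generating values for every synthetic observable.

    Only the fields relevant to the generator that produced the object are
    populated; ``params`` holds scalar generating parameters by name.
    """

    true_tracks: "object | None" = None          # DataFrame of per-frame truth
    true_diameter_series: np.ndarray | None = None   # (t_s, d_um) columns
    true_peak_times: dict = field(default_factory=dict)
    true_area_ratio: float | None = None
    true_modulation_depths: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)
    arrays: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# flow movie
# ---------------------------------------------------------------------------

@dataclass
class FlowScenario:
    """Parameters of a synthetic pulsatile PVS channel-flow movie.

    The channel is 2-D: width ``channel_width`` (the PVS width L) across y,
    length along x, with a parabolic no-slip profile whose spatiotemporal
    mean is ``mean_speed``. The flow is modulated over the cardiac cycle with
    the given depth and R-wave lag; ``backflow_amplitude`` is the fraction of
    each cycle spent with negative velocity. Brownian jitter uses the
    Stokes–Einstein diffusivity of a 1 µm sphere at 36.8 °C by default.
    """

    channel_width: float = 45.0        # µm (~ the 44 µm average PVS width)
    channel_length: float = 200.0      # µm
    mean_speed: float = 18.7           # µm/s
    cardiac_frequency: float = 5.0     # Hz
    cardiac_modulation_depth: float = 0.99
    cardiac_lag: float = 0.0345        # s, flow peak after R wave
    backflow_amplitude: float = 0.0    # fraction of cycle with reverse flow
    n_particles: int = 100
    stuck_fraction: float = 0.05
    diffusivity: float = 6.55e-13      # m²/s
    pixel_size: float = 1.0            # µm/px
    frame_rate: float = 30.0           # Hz
    noise_level: float = 10.0          # background photon counts
    jitter_amplitude: float = 0.0      # px rigid frame jitter (SD)
    duration: float = 30.0             # s
    beat_jitter: float = 0.004         # s, SD of inter-beat intervals
    seed: int = 0

    def validate(self) -> None:
        if self.mean_speed <= 0:
            raise ValueError("mean_speed must be positive")
        if not 0.0 <= self.stuck_fraction <= 1.0:
            raise ValueError("stuck_fraction must be in [0, 1]")
        if self.frame_rate <= 2 * self.cardiac_frequency:
            raise ValueError("frame_rate must exceed twice the cardiac frequency")
        if self.duration * self.cardiac_frequency < 2:
            raise ValueError("need at least two cardiac cycles for conditional averaging")


#: rendering constants: Gaussian particle image, σ = 1 px (no PSF model)
_SPOT_SIGMA_PX = 1.0
_SPOT_AMPLITUDE = 300.0
_SPOT_RADIUS_PX = 4
# margin is a whole number of 7.5 px analysis boxes so that the channel walls
# fall on box boundaries (the default width is too); partial wall boxes would
# otherwise over-weight the slow no-slip region in the equal-weight box mean
_MARGIN_PX = 15
_ARTERY_BAND_PX = 16
_ARTERY_GAP_PX = 4


def _render_spots(image: np.ndarray, cols: np.ndarray, rows: np.ndarray,
                  amplitude: float = _SPOT_AMPLITUDE) -> None:
    """Add isotropic Gaussian spots at subpixel (col, row) centers, in place."""
    ny, nx = image.shape
    r = _SPOT_RADIUS_PX
    offsets = np.arange(-r, r + 1)
    for c, q in zip(cols, rows):
        ic, iq = int(round(c)), int(round(q))
        if not (-r <= ic < nx + r and -r <= iq < ny + r):
            continue
        gx = np.exp(-((ic + offsets - c) ** 2) / (2 * _SPOT_SIGMA_PX ** 2))
        gy = np.exp(-((iq + offsets - q) ** 2) / (2 * _SPOT_SIGMA_PX ** 2))
        x0, x1 = max(ic - r, 0), min(ic + r + 1, nx)
        y0, y1 = max(iq - r, 0), min(iq + r + 1, ny)
        image[y0:y1, x0:x1] += amplitude * np.outer(
            gy[y0 - (iq - r): y1 - (iq - r)], gx[x0 - (ic - r): x1 - (ic - r)])


def generate_flow_movie(scenario: FlowScenario) -> tuple[ImageStack, GroundTruth]:
    """Synthesize a two-channel microsphere movie with full ground truth.

    Channel 0 is the (static, textured) vessel-dye channel, channel 1 the
    microsphere channel. Moving particles follow
    ``v(y, t) = 6 U (y/w)(1 − y/w) m(t)`` plus Brownian steps of variance
    ``2 D Δt`` per axis; a ``stuck_fraction`` of particles sits frozen at
    wall-adjacent positions; a recorded rigid jitter and Poisson photon noise
    are applied to the rendered frames.

    Ground truth stores per-frame positions and *advective* velocities for
    every particle, the R-peak times driving the modulation, the jitter
    series, and the realized negative-velocity fraction.
    """
    import pandas as pd

    scenario.validate()
    sc = scenario
    rng = np.random.default_rng(sc.seed)
    n_frames = int(round(sc.duration * sc.frame_rate))
    dt = 1.0 / sc.frame_rate
    w, L = sc.channel_width, sc.channel_length
    d_um2 = sc.diffusivity * _M2_TO_UM2
    step_sd = np.sqrt(2.0 * d_um2 * dt)

    beat_times = _peak_times(sc.cardiac_frequency, sc.duration, rng, sc.beat_jitter)
    peak_phase = sc.cardiac_lag * sc.cardiac_frequency
    modulation = flow_modulation(sc.cardiac_modulation_depth, peak_phase,
                                 sc.backflow_amplitude)

    def beat_phase(t: float) -> float:
        i = np.searchsorted(beat_times, t, side="right") - 1
        i = int(np.clip(i, 0, len(beat_times) - 2))
        return (t - beat_times[i]) / (beat_times[i + 1] - beat_times[i])

    n_stuck = int(round(sc.stuck_fraction * sc.n_particles))
    n_moving = sc.n_particles - n_stuck

    # moving particles: uniform over the channel
    x = rng.uniform(0.0, L, n_moving)
    y = rng.uniform(0.0, w, n_moving)
    ids = np.arange(n_moving)
    next_id = n_moving
    # stuck particles: frozen within 1 µm of either wall
    stuck_x = rng.uniform(0.0, L, n_stuck)
    stuck_y = np.where(rng.random(n_stuck) < 0.5,
                       rng.uniform(0.0, 1.0, n_stuck),
                       w - rng.uniform(0.0, 1.0, n_stuck))
    stuck_ids = np.arange(10_000_000, 10_000_000 + n_stuck)

    jitter = (rng.normal(0.0, sc.jitter_amplitude, (n_frames, 2))
              if sc.jitter_amplitude > 0 else np.zeros((n_frames, 2)))

    # image layout: channel wall y=0 at row _MARGIN_PX, artery band below
    w_px = int(round(w / sc.pixel_size))
    l_px = int(round(L / sc.pixel_size))
    ny = _MARGIN_PX + w_px + _ARTERY_GAP_PX + _ARTERY_BAND_PX + _MARGIN_PX
    nx = l_px + 2 * _MARGIN_PX

    # static vessel channel: bright artery band with sharp random texture so
    # registration can lock both axes. The scene extends beyond the frame
    # (pad) and a jittered window is cropped from it, as for a real camera:
    # frame jitter brings new content in at the edges, never a false border.
    pad = _SPOT_RADIUS_PX + int(np.ceil(3 * sc.jitter_amplitude)) + 2
    rows_big = np.arange(-pad, ny + pad)[:, None]
    band_top = _MARGIN_PX + w_px + _ARTERY_GAP_PX
    band = 1.0 / (1.0 + np.exp(-(rows_big - band_top) / 1.5)) \
        - 1.0 / (1.0 + np.exp(-(rows_big - band_top - _ARTERY_BAND_PX) / 1.5))
    texture = ndimage.gaussian_filter(rng.random((ny + 2 * pad, nx + 2 * pad)), 1.3)
    texture = (texture - texture.min()) / np.ptp(texture)
    vessel_big = sc.noise_level + 400.0 * band * (0.3 + 0.7 * texture) \
        + 60.0 * texture

    records: list[tuple] = []
    movie = np.zeros((n_frames, 2, ny, nx), dtype=np.uint16)

    for k in range(n_frames):
        t = k * dt
        m_t = float(modulation(beat_phase(t)))
        vx = 6.0 * sc.mean_speed * (y / w) * (1.0 - y / w) * m_t

        for pid, xi, yi, vi in zip(ids, x, y, vx):
            records.append((pid, k, t, xi, yi, vi, 0.0, False))
        for pid, xi, yi in zip(stuck_ids, stuck_x, stuck_y):
            records.append((pid, k, t, xi, yi, 0.0, 0.0, True))

        jx, jy = jitter[k]
        all_x = np.concatenate([x, stuck_x])
        all_y = np.concatenate([y, stuck_y])
        cols = all_x / sc.pixel_size + _MARGIN_PX + jx
        rws = all_y / sc.pixel_size + _MARGIN_PX + jy
        sphere_clean = np.full((ny, nx), float(sc.noise_level))
        _render_spots(sphere_clean, cols, rws)
        movie[k, 1] = np.clip(rng.poisson(sphere_clean), 0, 65535).astype(np.uint16)
        if sc.jitter_amplitude > 0:
            shifted = ndimage.shift(vessel_big, (jy, jx), order=1, mode="nearest")
        else:
            shifted = vessel_big
        vessel_view = shifted[pad:pad + ny, pad:pad + nx]
        movie[k, 0] = np.clip(rng.poisson(vessel_view), 0, 65535).astype(np.uint16)

        # advance moving particles
        x = x + vx * dt + rng.normal(0.0, step_sd, n_moving)
        y = y + rng.normal(0.0, step_sd, n_moving)
        y = np.abs(y)                        # reflect at both walls
        y = w - np.abs(w - y)
        left = x > L
        for i in np.flatnonzero(left):       # particle leaves downstream: new id enters
            x[i] -= L
            ids[i] = next_id
            next_id += 1
        x = np.clip(x, -1.0, L + 1.0)

    tracks = pd.DataFrame.from_records(
        records, columns=["track_id", "frame", "t_s", "x_um", "y_um",
                          "ux_um_s", "uy_um_s", "stuck"])
    moving = tracks[~tracks["stuck"]]
    realized_backflow = (float(np.mean(moving["ux_um_s"] < 0))
                         if len(moving) else 0.0)
    mean_true_speed = (float(np.mean(np.hypot(moving["ux_um_s"], moving["uy_um_s"])))
                       if len(moving) else 0.0)
    truth = GroundTruth(
        true_tracks=tracks,
        true_peak_times={"ecg": beat_times},
        true_modulation_depths={"cardiac": 100.0 * sc.cardiac_modulation_depth},
        params={
            "mean_speed": sc.mean_speed,
            "mean_true_speed": mean_true_speed,
            "backflow_fraction_target": sc.backflow_amplitude,
            "backflow_fraction_realized": realized_backflow,
            "margin_px": _MARGIN_PX,
            "channel_width_px": w_px,
        },
        arrays={
            "jitter_px": jitter,
            "stuck_x_um": stuck_x,
            "stuck_y_um": stuck_y,
        },
    )
    stack = ImageStack(data=movie, pixel_size=sc.pixel_size, frame_rate=sc.frame_rate)
    return stack, truth


# ---------------------------------------------------------------------------
# physiological traces
# ---------------------------------------------------------------------------

def generate_physio(cardiac_frequency: float = 5.0,
                    respiratory_frequency: float = 1.7,
                    duration: float = 60.0,
                    sample_rates: tuple[float, float] = (1000.0, 250.0),
                    seed: int = 0,
                    interval_jitter: float = 0.0,
                    noise_level: float = 0.02,
                    pressure_mmhg: float | None = None) -> tuple[PhysioRecord, GroundTruth]:
    """Synthesize ECG and respiration traces with exactly known peak times.

    The ECG is a train of narrow R-wave spikes on baseline noise; respiration
    is a smooth peaked waveform. Peak times are snapped to the respective
    sample grids so that noise-free detection recovers them exactly.
    An optional constant arterial-pressure trace carries a condition label
    (normotensive / hypertensive mean) for condition comparisons.
    """
    if not cardiac_frequency > respiratory_frequency > 0:
        raise ValueError("require cardiac_frequency > respiratory_frequency > 0")
    if duration < 1.0 / respiratory_frequency:
        raise ValueError("duration shorter than one respiratory cycle")
    rng = np.random.default_rng(seed)
    ecg_rate, resp_rate = sample_rates

    r_times = _peak_times(cardiac_frequency, duration, rng, interval_jitter)
    r_times = np.round(r_times * ecg_rate) / ecg_rate        # snap to ECG grid
    r_times = np.unique(r_times[r_times < duration])
    t_ecg = np.arange(int(round(duration * ecg_rate))) / ecg_rate
    ecg = rng.normal(0.0, noise_level, len(t_ecg)) if noise_level > 0 else np.zeros(len(t_ecg))
    for rt in r_times:                                       # 4 ms wide R spikes
        ecg += np.exp(-0.5 * ((t_ecg - rt) / 0.002) ** 2)

    resp_times = _peak_times(respiratory_frequency, duration, rng, interval_jitter)
    resp_times = np.round(resp_times * resp_rate) / resp_rate
    resp_times = np.unique(resp_times[resp_times < duration])
    t_resp = np.arange(int(round(duration * resp_rate))) / resp_rate
    resp_phase = np.interp(t_resp, resp_times, np.arange(len(resp_times)))
    resp = periodic_bump(resp_phase, 0.0, 3)
    if noise_level > 0:
        resp = resp + rng.normal(0.0, noise_level, len(t_resp))

    pressure = None
    if pressure_mmhg is not None:
        t_p = np.arange(int(round(duration * resp_rate))) / resp_rate
        pressure = pressure_mmhg + rng.normal(0.0, 0.5, len(t_p))

    record = PhysioRecord(ecg=ecg, ecg_rate=ecg_rate,
                          respiration=resp, respiration_rate=resp_rate,
                          pressure=pressure,
                          pressure_rate=resp_rate if pressure is not None else None)
    truth = GroundTruth(
        true_peak_times={"ecg": r_times, "respiration": resp_times},
        params={
            "cardiac_frequency": cardiac_frequency,
            "respiratory_frequency": respiratory_frequency,
            "interval_jitter": interval_jitter,
            "pressure_mmhg": pressure_mmhg if pressure_mmhg is not None else np.nan,
        },
    )
    return record, truth


# ---------------------------------------------------------------------------
# wall line scans
# ---------------------------------------------------------------------------

@dataclass
class WallScenario:
    """Parameters of a synthetic transverse line-scan (kymograph) recording.

    ``waveform_shape`` selects the diameter-change waveform over the cardiac
    cycle: ``"fast-rise-slow-fall"`` (a narrow systolic expansion pulse and a
    broad diastolic recovery, band-limited to 8 harmonics), ``"sinusoid"``,
    or ``"custom"`` (phase-periodic samples in ``custom_waveform``).
    ``wall_lag`` places the peak of the wall *velocity* after the R wave.
    """

    baseline_diameter: float = 50.0    # µm
    pulse_amplitude: float = 0.8       # µm, peak Δd
    waveform_shape: str = "fast-rise-slow-fall"
    custom_waveform: np.ndarray | None = None
    cardiac_frequency: float = 5.0     # Hz
    wall_lag: float = 0.0345           # s, wall-velocity peak after R wave
    linescan_rate: float = 600.0       # Hz
    duration: float = 45.0             # s
    n_pixels: int = 128
    pixel_size: float = 1.0            # µm/px
    edge_sharpness: float = 1.5        # px
    noise_level: float = 0.02          # fraction of plateau intensity
    beat_jitter: float = 0.0           # s
    seed: int = 0

    def validate(self) -> None:
        if not 0 <= self.pulse_amplitude < self.baseline_diameter:
            raise ValueError("need 0 <= pulse_amplitude < baseline_diameter")
        if self.linescan_rate < 10 * self.cardiac_frequency:
            raise ValueError("linescan_rate must greatly exceed the cardiac frequency")
        if self.baseline_diameter / self.pixel_size > 0.8 * self.n_pixels:
            raise ValueError("artery does not fit in the scan line")

    @classmethod
    def for_peak_wall_velocity(cls, peak_wall_velocity: float,
                               wall_lag: float = 0.0345, **kwargs) -> "WallScenario":
        """Scenario whose ground-truth peak wall velocity equals the target (µm/s)."""
        probe = cls(pulse_amplitude=1.0, wall_lag=wall_lag, **kwargs)
        _, vel = _waveform_functions(probe)
        grid = np.linspace(0.0, 1.0, 4096, endpoint=False)
        peak = float(np.max(vel(grid)))
        return cls(pulse_amplitude=peak_wall_velocity / peak, wall_lag=wall_lag, **kwargs)


def _waveform_functions(sc: WallScenario):
    """(Δd(phase) µm, wall-velocity(phase) µm/s) for a wall scenario.

    The fast-rise/slow-fall velocity shape is a cos^16 systolic pulse minus a
    broad cos^4 recovery lobe in antiphase (zero cycle mean); the diameter
    change is its exact analytic antiderivative, so both are band-limited to
    8 harmonics and the stored ground truth is exact.
    """
    f = sc.cardiac_frequency
    lag_phase = sc.wall_lag * f

    if sc.waveform_shape == "sinusoid":
        def delta(phase):
            return sc.pulse_amplitude * np.sin(2 * np.pi * (np.asarray(phase) - lag_phase))

        def vel(phase):
            return (sc.pulse_amplitude * 2 * np.pi * f
                    * np.cos(2 * np.pi * (np.asarray(phase) - lag_phase)))

        return delta, vel

    if sc.waveform_shape == "custom":
        if sc.custom_waveform is None:
            raise ValueError("custom waveform_shape requires custom_waveform samples")
        samples = np.asarray(sc.custom_waveform, float)
        samples = samples - samples.mean()
        phases = np.arange(len(samples)) / len(samples)

        def delta(phase):
            return sc.pulse_amplitude * np.interp(
                np.mod(phase, 1.0), phases, samples, period=1.0)

        grid = np.linspace(0.0, 1.0, 4096, endpoint=False)
        dvals = delta(grid)
        vvals = np.gradient(dvals, grid, edge_order=2) * f

        def vel(phase):
            return np.interp(np.mod(phase, 1.0), grid, vvals, period=1.0)

        return delta, vel

    if sc.waveform_shape != "fast-rise-slow-fall":
        raise ValueError(f"unknown waveform_shape {sc.waveform_shape!r}")

    p_rise, p_fall = 8, 2
    c = periodic_bump_mean(p_rise) / periodic_bump_mean(p_fall)

    def vshape(phase):
        return (periodic_bump(phase, lag_phase, p_rise)
                - c * periodic_bump(phase, lag_phase + 0.5, p_fall))

    # analytic antiderivative via the harmonic expansion of cos^(2p)
    def _coeffs(p):
        return {k: 2 * comb(2 * p, p - k) / 4.0 ** p for k in range(1, p + 1)}

    rise_c, fall_c = _coeffs(p_rise), _coeffs(p_fall)

    def dshape(phase):
        phase = np.asarray(phase, float)
        out = np.zeros_like(phase)
        for k, a in rise_c.items():
            out += a * np.sin(2 * np.pi * k * (phase - lag_phase)) / (2 * np.pi * k)
        for k, a in fall_c.items():
            out -= c * a * np.sin(2 * np.pi * k * (phase - lag_phase - 0.5)) / (2 * np.pi * k)
        return out

    grid = np.linspace(0.0, 1.0, 4096, endpoint=False)
    dvals = dshape(grid)
    scale = sc.pulse_amplitude / dvals.max()

    def delta(phase):
        return scale * dshape(phase)

    def vel(phase):
        return scale * f * vshape(phase)

    return delta, vel


def generate_linescan(scenario: WallScenario) -> tuple[np.ndarray, GroundTruth]:
    """Synthesize a line-scan kymograph of a pulsating artery.

    Each scan line is a smoothed top-hat intensity profile whose edges sit at
    ``center ± d(t)/2`` with ``d(t) = baseline + Δd(cardiac phase)``.
    Ground truth stores the full diameter series, the driving R-peak times,
    the exact Δd/velocity waveforms on a fine phase grid, and the peak wall
    velocity with its delay after the R wave.
    """
    scenario.validate()
    sc = scenario
    rng = np.random.default_rng(sc.seed)
    delta, vel = _waveform_functions(sc)

    beat_times = _peak_times(sc.cardiac_frequency, sc.duration, rng, sc.beat_jitter)
    n_lines = int(round(sc.duration * sc.linescan_rate))
    t = np.arange(n_lines) / sc.linescan_rate
    idx = np.clip(np.searchsorted(beat_times, t, side="right") - 1, 0, len(beat_times) - 2)
    phase = (t - beat_times[idx]) / (beat_times[idx + 1] - beat_times[idx])

    d = sc.baseline_diameter + delta(phase)                    # µm
    center = sc.n_pixels / 2.0
    left = center - d / (2.0 * sc.pixel_size)
    right = center + d / (2.0 * sc.pixel_size)

    xpix = np.arange(sc.n_pixels)[None, :]
    s = sc.edge_sharpness
    amp = 1000.0
    profile = amp * (1.0 / (1.0 + np.exp(-(xpix - left[:, None]) / s))
                     - 1.0 / (1.0 + np.exp(-(xpix - right[:, None]) / s)))
    if sc.noise_level > 0:
        profile = profile + rng.normal(0.0, sc.noise_level * amp, profile.shape)

    fine = np.linspace(0.0, 1.0, 4096, endpoint=False)
    vfine = vel(fine)
    ipk = int(np.argmax(vfine))
    truth = GroundTruth(
        true_diameter_series=np.column_stack([t, d]),
        true_peak_times={"ecg": beat_times},
        params={
            "baseline_diameter": sc.baseline_diameter,
            "pulse_amplitude": sc.pulse_amplitude,
            "peak_wall_velocity": float(vfine[ipk]),
            "wall_velocity_lag": float(fine[ipk] / sc.cardiac_frequency),
            "samples_per_cycle": sc.linescan_rate / sc.cardiac_frequency,
        },
        arrays={
            "phase_grid": fine,
            "delta_waveform_um": delta(fine),
            "velocity_waveform_um_s": vfine,
        },
    )
    return profile, truth


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def generate_geometry(true_area_ratio: float, artery_radius_px: float = 14.0,
                      image_shape: tuple[int, int] = (192, 192),
                      elongation: float = 3.5, n_positions: int = 2000,
                      seed: int = 0):
    """Construct artery/PVS masks with a prescribed area ratio and sample tracers.

    The artery is an ellipse (cross-half-width ``artery_radius_px``, half-length
    ``elongation`` times that) flanked by two non-overlapping PVS lobes whose
    total pixel count is ``true_area_ratio`` times the rasterized artery area
    (exact to ±1 px). ``n_positions`` particle positions are sampled uniformly
    over the PVS mask with subpixel offsets.

    Returns ``(artery_mask, pvs_mask, positions, truth)`` where ``positions``
    is an (N, 2) array of (x, y) pixel coordinates and ``truth`` carries the
    realized ratio and the ROI (artery ∪ PVS) used for reproducible
    area-ratio computation.
    """
    if true_area_ratio <= 0:
        raise ValueError("true_area_ratio must be positive")
    ny, nx = image_shape
    b = float(artery_radius_px)
    a = elongation * b
    cy, cx = ny / 2.0, nx / 2.0
    yy, xx = np.mgrid[0:ny, 0:nx]
    artery = ((yy - cy) / a) ** 2 + ((xx - cx) / b) ** 2 <= 1.0
    artery_area = int(artery.sum())

    row0 = int(np.ceil(cy - a))
    row1 = int(np.floor(cy + a))
    height = row1 - row0
    if height <= 0:
        raise ValueError("artery too small for the image")
    target_per_lobe = int(round(true_area_ratio * artery_area / 2.0))
    n_cols = int(np.ceil(target_per_lobe / height))
    left_edge = int(np.floor(cx - b)) - 1
    right_edge = int(np.ceil(cx + b)) + 1
    if left_edge - n_cols < 0 or right_edge + n_cols >= nx:
        raise ValueError("area ratio too large: PVS lobes exceed image bounds")

    pvs = np.zeros((ny, nx), dtype=bool)
    for sign, edge in ((-1, left_edge), (+1, right_edge)):
        remaining = target_per_lobe
        col = edge
        while remaining > 0:
            fill = min(height, remaining)
            pvs[row0:row0 + fill, col] = True
            remaining -= fill
            col += sign

    rng = np.random.default_rng(seed)
    flat = np.flatnonzero(pvs)
    chosen = rng.choice(flat, size=n_positions, replace=True)
    rows, cols = np.unravel_index(chosen, pvs.shape)
    positions = np.column_stack([
        cols + rng.uniform(-0.5, 0.5, n_positions),
        rows + rng.uniform(-0.5, 0.5, n_positions),
    ])

    realized = pvs.sum() / artery_area
    truth = GroundTruth(
        true_area_ratio=float(realized),
        params={
            "requested_ratio": true_area_ratio,
            "artery_area_px": artery_area,
            "pvs_area_px": int(pvs.sum()),
            "lobe_width_px": float(target_per_lobe / height),
            "lobe_height_px": height,
        },
        arrays={"roi": artery | pvs},
    )
    return artery, pvs, positions, truth


# ---------------------------------------------------------------------------
# direct v_rms synthesis
# ---------------------------------------------------------------------------

def generate_vrms_series(duration: float = 120.0, sample_rate: float = 30.0,
                         cardiac_frequency: float = 5.0,
                         respiratory_frequency: float = 1.7,
                         cardiac_depth: float = 0.99,
                         respiratory_depth: float = 0.22,
                         cardiac_lag: float = 0.0345,
                         base_level: float = 20.0,
                         noise_level: float = 0.03,
                         interval_jitter: float = 0.010,
                         seed: int = 0):
    """Synthesize a v_rms time series locked to synthetic ECG and respiration.

    v_rms(t) = base · m_c(cardiac phase) · m_r(respiratory phase) + noise,
    with both modulation factors of unit mean and prescribed (max−min)/max
    depths, the cardiac factor peaking ``cardiac_lag`` after each R wave.
    Negative noise excursions are clipped at zero (v_rms is non-negative).

    Returns ``(times, vrms, record, truth)`` with a peak-populated
    :class:`~pvsflow.physio_sync.PhysioRecord`.
    """
    record, ptruth = generate_physio(cardiac_frequency, respiratory_frequency,
                                     duration, seed=seed,
                                     interval_jitter=interval_jitter)
    record.r_peak_times = ptruth.true_peak_times["ecg"]
    record.respiration_peak_times = ptruth.true_peak_times["respiration"]

    rng = np.random.default_rng(seed + 1)
    times = np.arange(int(round(duration * sample_rate))) / sample_rate

    def phase_of(t, peaks):
        idx = np.clip(np.searchsorted(peaks, t, side="right") - 1, 0, len(peaks) - 2)
        return (t - peaks[idx]) / (peaks[idx + 1] - peaks[idx])

    m_c = cardiac_modulation_waveform(cardiac_depth,
                                      peak_phase=cardiac_lag * cardiac_frequency,
                                      pulse_power=3)
    m_r = cardiac_modulation_waveform(respiratory_depth, peak_phase=0.3,
                                      pulse_power=2)
    vrms = base_level * m_c(phase_of(times, record.r_peak_times)) \
        * m_r(phase_of(times, record.respiration_peak_times))
    if noise_level > 0:
        vrms = np.clip(vrms + rng.normal(0.0, noise_level * base_level, len(vrms)), 0.0, None)

    truth = GroundTruth(
        true_peak_times=ptruth.true_peak_times,
        true_modulation_depths={"cardiac": 100.0 * cardiac_depth,
                                "respiratory": 100.0 * respiratory_depth},
        params={"base_level": base_level, "cardiac_lag": cardiac_lag},
    )
    return times, vrms, record, truth
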