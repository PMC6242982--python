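"""Artery diameter from line-scan kymographs and cardiac-phase wall kinematics.

Each scan line is a bright plateau whose outer edges are located with
subpixel precision by cubic interpolation and threshold crossing; the
threshold sits at the steepest-gradient intensity of the time-averaged
profile. The diameter change Δd (instantaneous minus a two-cardiac-cycle
moving average) is binned over the cardiac cycle, normalized by the mean
diameter, fit with a high-order Fourier series, and differentiated
analytically to give the arterial wall velocity waveform, its peak, and the
delay of that peak after the R wave.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.ndimage import gaussian_filter1d

from .physio_sync import cycle_phase


@dataclass
class DiameterSeries:
    """Instantaneous artery diameter and its cardiac-detrended change."""

    time: np.ndarray           # s
    diameter: np.ndarray       # µm; NaN flags failed edge extraction
    moving_average: np.ndarray | None = None   # two-cardiac-cycle window, µm
    delta: np.ndarray | None = None            # Δd = d − moving average, µm

    @property
    def mean_diameter(self) -> float:
        return float(np.nanmean(self.diameter))


@dataclass
class DiameterWaveform:
    """Cardiac-phase-binned Δd waveform, its Fourier fit and wall velocity."""

    phase_centers: np.ndarray      # ∈ [0, 1)
    delta_um: np.ndarray           # mean Δd per bin; NaN flags empty bins
    delta_normalized: np.ndarray   # Δd / d
    count: np.ndarray
    mean_diameter: float
    fourier_coefficients: np.ndarray | None = None   # [a0, a1..aK, b1..bK]
    cardiac_period: float | None = None              # s
    velocity_phase: np.ndarray | None = None
    velocity_um_s: np.ndarray | None = None          # wall velocity waveform
    peak_velocity: float | None = None               # µm/s
    peak_delay_ms: float | None = None               # after the R peak


def diameter_from_profile(profile: np.ndarray, threshold: float,
                          upsample_factor: int = 10) -> float:
    """Artery diameter (px) from one scan line by subpixel threshold crossing.

    The intensity profile is cubic-interpolated onto an ``upsample_factor``
    finer grid; the outermost upward and downward crossings of the threshold
    bound the bright plateau, and the diameter is the distance between them.
    Returns NaN (a flagged missing sample) when fewer than two crossings exist.
    """
    profile = np.asarray(profile, float)
    x = np.arange(len(profile))
    fine_x = np.linspace(0, len(profile) - 1, (len(profile) - 1) * upsample_factor + 1)
    fine = CubicSpline(x, profile)(fine_x)
    s = fine - threshold
    sign_change = np.flatnonzero(np.diff(np.signbit(s)))
    if len(sign_change) < 2:
        return np.nan
    up = [i for i in sign_change if s[i] < s[i + 1]]
    down = [i for i in sign_change if s[i] > s[i + 1]]
    if not up or not down:
        return np.nan
    def _cross(i):
        return fine_x[i] + (0.0 - s[i]) / (s[i + 1] - s[i]) * (fine_x[i + 1] - fine_x[i])
    left = _cross(up[0])
    right = _cross(down[-1])
    if right <= left:
        return np.nan
    return float(right - left)


def choose_threshold(profiles: np.ndarray, smooth_px: float = 1.0) -> float:
    """Edge threshold: intensity of the time-averaged profile at its steepest gradient."""
    profiles = np.atleast_2d(np.asarray(profiles, float))
    if profiles.shape[0] < 10:
        raise ValueError("need at least 10 scan lines to choose a threshold")
    mean_profile = profiles.mean(axis=0)
    smooth = gaussian_filter1d(mean_profile, smooth_px)
    grad = np.abs(np.gradient(smooth))
    if grad.max() == 0:
        raise ValueError("flat profile: no gradient maximum")
    # a linear edge has a constant-gradient plateau: take the middle of the
    # plateau containing the global maximum (not of all near-maximal edges)
    i0 = int(np.argmax(grad))
    lo = hi = i0
    while lo > 0 and grad[lo - 1] >= 0.999 * grad[i0]:
        lo -= 1
    while hi < len(grad) - 1 and grad[hi + 1] >= 0.999 * grad[i0]:
        hi += 1
    return float(mean_profile[(lo + hi) // 2])


def extract_diameter_series(kymograph: np.ndarray, rate: float, pixel_size: float,
                            threshold: float | None = None,
                            upsample_factor: int = 10,
                            max_gap: int = 5) -> DiameterSeries:
    """Diameter (µm) for every scan line of a kymograph.

    Failed edge extractions are linearly interpolated when the gap is at most
    ``max_gap`` samples, and left NaN-flagged otherwise.
    """
    kymo = np.asarray(kymograph, float)
    if threshold is None:
        threshold = choose_threshold(kymo)
    d_px = np.array([diameter_from_profile(line, threshold, upsample_factor)
                     for line in kymo])
    d_px = _fill_short_gaps(d_px, max_gap)
    return DiameterSeries(time=np.arange(len(d_px)) / rate,
                          diameter=d_px * pixel_size)


def _fill_short_gaps(values: np.ndarray, max_gap: int) -> np.ndarray:
    bad = ~np.isfinite(values)
    if not bad.any() or bad.all():
        return values
    out = values.copy()
    idx = np.arange(len(values))
    # identify runs of consecutive missing samples
    starts = np.flatnonzero(bad & ~np.roll(bad, 1))
    if bad[0]:
        starts = np.unique(np.concatenate([[0], starts]))
    for start in starts:
        end = start
        while end < len(values) and bad[end]:
            end += 1
        if end - start <= max_gap and start > 0 and end < len(values):
            out[start:end] = np.interp(idx[start:end], [start - 1, end],
                                       [values[start - 1], values[end]])
    return out


def delta_diameter(series: DiameterSeries, r_peak_times: np.ndarray) -> DiameterSeries:
    """Δd: diameter minus a centered two-cardiac-cycle moving average.

    The window spans two median R-R intervals; samples where the window is
    incomplete (record edges) are NaN-flagged.
    """
    r_peaks = np.asarray(r_peak_times, float)
    if len(r_peaks) < 4:
        raise ValueError("need at least 3 cardiac cycles for the moving average")
    dt = float(np.median(np.diff(series.time)))
    window = int(round(2.0 * np.median(np.diff(r_peaks)) / dt))
    window = max(window + (1 - window % 2), 3)          # odd, ≥3
    avg = (pd.Series(series.diameter)
           .rolling(window, center=True, min_periods=window)
           .mean()
           .to_numpy())
    series.moving_average = avg
    series.delta = series.diameter - avg
    return series


def phase_waveform(series: DiameterSeries, r_peak_times: np.ndarray,
                   n_bins: int = 50) -> DiameterWaveform:
    """Bin Δd by cardiac phase and normalize by the record-mean diameter."""
    if series.delta is None:
        raise ValueError("run delta_diameter first")
    phase = cycle_phase(series.time, np.asarray(r_peak_times, float))
    keep = np.isfinite(phase) & np.isfinite(series.delta)
    bins = np.clip((phase[keep] * n_bins).astype(int), 0, n_bins - 1)
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins)
    np.add.at(sums, bins, series.delta[keep])
    np.add.at(counts, bins, 1)
    delta = np.full(n_bins, np.nan)
    np.divide(sums, counts, out=delta, where=counts > 0)
    d_mean = series.mean_diameter
    return DiameterWaveform(phase_centers=(np.arange(n_bins) + 0.5) / n_bins,
                            delta_um=delta, delta_normalized=delta / d_mean,
                            count=counts.astype(int), mean_diameter=d_mean)


def fit_fourier(phases: np.ndarray, values: np.ndarray, order: int = 8) -> np.ndarray:
    """Least-squares Fourier series fit a0 + Σ ak cos(2πkφ) + bk sin(2πkφ).

    Returns coefficients ``[a0, a1..aK, b1..bK]``. NaN values (empty bins)
    are dropped before fitting.
    """
    phases = np.asarray(phases, float)
    values = np.asarray(values, float)
    keep = np.isfinite(values)
    phases, values = phases[keep], values[keep]
    if len(values) < 2 * order + 1:
        raise ValueError("need at least 2*order+1 bins for the fit")
    k = np.arange(1, order + 1)
    design = np.hstack([
        np.ones((len(phases), 1)),
        np.cos(2 * np.pi * np.outer(phases, k)),
        np.sin(2 * np.pi * np.outer(phases, k)),
    ])
    coef, _, rank, _ = np.linalg.lstsq(design, values, rcond=None)
    if rank < design.shape[1]:
        raise ValueError("singular Fourier design (duplicate or missing phases)")
    return coef


def evaluate_fourier(coef: np.ndarray, phases: np.ndarray) -> np.ndarray:
    order = (len(coef) - 1) // 2
    k = np.arange(1, order + 1)
    a, b = coef[1:order + 1], coef[order + 1:]
    arg = 2 * np.pi * np.outer(np.asarray(phases, float), k)
    return coef[0] + np.cos(arg) @ a + np.sin(arg) @ b


def wall_velocity(coef: np.ndarray, cardiac_period: float,
                  n_grid: int = 1000) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Analytic derivative of the fitted Δd waveform: the wall velocity.

    Term-wise differentiation of the Fourier series, evaluated on a fine
    phase grid and scaled by 1/period to µm/s. Returns
    ``(phase_grid, velocity, peak_velocity, peak_delay_ms)`` with the delay
    of the velocity peak after phase 0 (the R peak) in milliseconds.
    """
    if cardiac_period <= 0:
        raise ValueError("cardiac period must be positive")
    order = (len(coef) - 1) // 2
    k = np.arange(1, order + 1)
    a, b = coef[1:order + 1], coef[order + 1:]
    phase = np.arange(n_grid) / n_grid
    arg = 2 * np.pi * np.outer(phase, k)
    velocity = (( -np.sin(arg) @ (2 * np.pi * k * a)
                 + np.cos(arg) @ (2 * np.pi * k * b)) / cardiac_period)
    ipk = int(np.argmax(velocity))
    return phase, velocity, float(velocity[ipk]), float(phase[ipk] * cardiac_period * 1e3)


def analyze_kymograph(kymograph: np.ndarray, rate: float, pixel_size: float,
                      r_peak_times: np.ndarray, n_bins: int = 50,
                      fourier_order: int = 8,
                      threshold: float | None = None,
                      upsample_factor: int = 10) -> DiameterWaveform:
    """Full wall-kinematics chain: kymograph → fitted waveform + wall velocity."""
    series = extract_diameter_series(kymograph, rate, pixel_size,
                                     threshold=threshold,
                                     upsample_factor=upsample_factor)
    series = delta_diameter(series, r_peak_times)
    waveform = phase_waveform(series, r_peak_times, n_bins=n_bins)
    coef = fit_fourier(waveform.phase_centers, waveform.delta_um, order=fourier_order)
    period = float(np.median(np.diff(r_peak_times)))
    phase, velocity, peak, delay_ms = wall_velocity(coef, period)
    waveform.fourier_coefficients = coef
    waveform.cardiac_period = period
    waveform.velocity_phase = phase
    waveform.velocity_um_s = velocity
    waveform.peak_velocity = peak
    waveform.peak_delay_ms = delay_ms
    return waveform
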