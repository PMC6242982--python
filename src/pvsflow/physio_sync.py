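"""Cardiac/respiratory peak detection, phase assignment and conditional averaging.

The cardiac cycle is defined by sequential R-wave peaks of the ECG; every
flow-intensity sample (v_rms) is assigned a cardiac phase and a respiratory
phase and conditionally averaged over both cycles. Delay-time distributions
between reference (ECG/respiration) peaks and the next v_rms peak, modulation
depths of the phase-averaged marginals, and plain power spectra round out the
module.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.ndimage import gaussian_filter1d


class PeakDetectionError(RuntimeError):
    """No usable peaks could be found in a physiological trace."""


@dataclass
class PhysioRecord:
    """Synchronized physiological traces and their detected peak times.

    ECG is sampled at ``ecg_rate`` Hz (1 kHz in the recordings this models),
    respiration at ``respiration_rate`` Hz (250 Hz), arterial pressure is
    optional. Peak times are in seconds from the start of the record.
    """

    ecg: np.ndarray
    ecg_rate: float
    respiration: np.ndarray | None = None
    respiration_rate: float | None = None
    pressure: np.ndarray | None = None
    pressure_rate: float | None = None
    r_peak_times: np.ndarray | None = None
    respiration_peak_times: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.ecg_rate <= 0:
            raise ValueError("ecg_rate must be positive")
        for times in (self.r_peak_times, self.respiration_peak_times):
            if times is not None and np.any(np.diff(times) <= 0):
                raise ValueError("peak times must be strictly increasing")

    def detect_peaks(self, **kwargs) -> "PhysioRecord":
        """Detect R peaks (and respiration peaks if present) in place."""
        self.r_peak_times = detect_r_peaks(self.ecg, self.ecg_rate, **kwargs)
        if self.respiration is not None:
            self.respiration_peak_times = detect_respiration_peaks(
                self.respiration, self.respiration_rate)
        return self


@dataclass
class DelayDistribution:
    """Probability density of delays between reference peaks and the next series peak."""

    bin_edges: np.ndarray     # s
    density: np.ndarray       # 1/s, one entry per bin
    n_pairs: int
    n_dropped: int = 0

    def __post_init__(self) -> None:
        if np.any(self.density < 0):
            raise ValueError("density must be non-negative")

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def mode_delay(self) -> float:
        """Center of the highest-density bin, in seconds."""
        return float(self.bin_centers[int(np.argmax(self.density))])


@dataclass
class ConditionalAverage:
    """v_rms conditionally averaged over the cardiac and respiratory cycles."""

    cardiac_bin_centers: np.ndarray
    respiratory_bin_centers: np.ndarray
    mean_2d: np.ndarray        # (cardiac, respiratory); NaN where the bin is empty
    count_2d: np.ndarray
    cardiac_marginal: np.ndarray = field(init=False)
    respiratory_marginal: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        # Marginals average the 2-D surface uniformly over the *other*
        # cycle's defined bins. This decouples the two rhythms: a direct
        # (count-weighted) phase average lets the strong cardiac modulation
        # leak into the respiratory marginal whenever the cardiac phase is
        # sampled unevenly within a respiratory bin, which inflates the
        # apparent respiratory modulation on records of finite length.
        with np.errstate(invalid="ignore"):
            self.cardiac_marginal = np.nanmean(self.mean_2d, axis=1)
            self.respiratory_marginal = np.nanmean(self.mean_2d, axis=0)

    def weighted_marginals(self) -> tuple[np.ndarray, np.ndarray]:
        """Count-weighted (direct phase-average) marginals, (cardiac, respiratory).

        These reproduce the plain one-cycle binned averages exactly; the
        count-weighted row/column means of the 2-D surface are consistent
        with them by construction.
        """
        return (_weighted_marginal(self.mean_2d, self.count_2d, axis=1),
                _weighted_marginal(self.mean_2d, self.count_2d, axis=0))

    @property
    def cardiac_modulation_depth(self) -> float:
        return modulation_depth(self.cardiac_marginal)

    @property
    def respiratory_modulation_depth(self) -> float:
        return modulation_depth(self.respiratory_marginal)


def _weighted_marginal(mean_2d: np.ndarray, count_2d: np.ndarray, axis: int) -> np.ndarray:
    weights = np.where(np.isnan(mean_2d), 0, count_2d)
    sums = np.nansum(mean_2d * weights, axis=axis)
    totals = weights.sum(axis=axis)
    out = np.full(sums.shape, np.nan)
    np.divide(sums, totals, out=out, where=totals > 0)
    return out


def detect_r_peaks(ecg: np.ndarray, rate: float, threshold_k: float = 2.0,
                   refractory_s: float = 0.05) -> np.ndarray:
    """Detect R-wave peak times in an ECG trace.

    Local maxima above ``mean + threshold_k * SD`` separated by at least the
    refractory period. Times are returned at sample resolution (seconds).
    """
    ecg = np.asarray(ecg, float)
    if len(ecg) < 2 * rate:
        raise ValueError("need at least 2 s of ECG signal")
    height = ecg.mean() + threshold_k * ecg.std()
    if ecg.std() == 0:
        raise PeakDetectionError("flat ECG signal, no peaks")
    distance = max(1, int(round(refractory_s * rate)))
    peaks, _ = signal.find_peaks(ecg, height=height, distance=distance)
    if len(peaks) == 0:
        raise PeakDetectionError("no R peaks above threshold")
    return peaks / rate


def detect_respiration_peaks(resp: np.ndarray, rate: float, threshold_k: float = 1.0,
                             refractory_s: float = 0.25,
                             smooth_s: float = 0.02) -> np.ndarray:
    """Respiration peak times; the R-peak detector in a lower frequency band.

    The trace is lightly smoothed before detection and a longer refractory
    period is used, matching the slower respiratory rhythm.
    """
    resp = np.asarray(resp, float)
    if smooth_s > 0:
        resp = gaussian_filter1d(resp, sigma=smooth_s * rate)
    return detect_r_peaks(resp, rate, threshold_k=threshold_k, refractory_s=refractory_s)


def cycle_phase(t: np.ndarray, peak_times: np.ndarray) -> np.ndarray:
    """Fraction of the cycle at each time: (t - previous peak)/(inter-peak interval).

    Times outside the [first, last] peak span get NaN (excluded from averages).
    """
    t = np.atleast_1d(np.asarray(t, float))
    peaks = np.asarray(peak_times, float)
    if len(peaks) < 2:
        raise ValueError("need at least two peaks to define a cycle")
    idx = np.searchsorted(peaks, t, side="right") - 1
    inside = (idx >= 0) & (idx < len(peaks) - 1)
    phase = np.full(t.shape, np.nan)
    i = idx[inside]
    phase[inside] = (t[inside] - peaks[i]) / (peaks[i + 1] - peaks[i])
    return phase


def conditional_average(vrms_values: np.ndarray, times: np.ndarray,
                        cardiac_peaks: np.ndarray, respiration_peaks: np.ndarray,
                        n_bins: tuple[int, int] = (25, 10)) -> ConditionalAverage:
    """Conditionally average a v_rms series over cardiac and respiratory phase.

    Each sample is assigned a (cardiac phase, respiratory phase) pair; samples
    with an undefined phase or a flagged (NaN) v_rms are dropped. Empty bins
    are NaN, never zero-filled.
    """
    values = np.asarray(vrms_values, float)
    times = np.asarray(times, float)
    phase_c = cycle_phase(times, cardiac_peaks)
    phase_r = cycle_phase(times, respiration_peaks)
    keep = np.isfinite(values) & np.isfinite(phase_c) & np.isfinite(phase_r)
    nc, nr = n_bins
    ic = np.clip((phase_c[keep] * nc).astype(int), 0, nc - 1)
    ir = np.clip((phase_r[keep] * nr).astype(int), 0, nr - 1)
    sums = np.zeros((nc, nr))
    counts = np.zeros((nc, nr))
    np.add.at(sums, (ic, ir), values[keep])
    np.add.at(counts, (ic, ir), 1)
    mean_2d = np.full((nc, nr), np.nan)
    np.divide(sums, counts, out=mean_2d, where=counts > 0)
    centers = lambda n: (np.arange(n) + 0.5) / n
    return ConditionalAverage(
        cardiac_bin_centers=centers(nc),
        respiratory_bin_centers=centers(nr),
        mean_2d=mean_2d,
        count_2d=counts,
    )


def modulation_depth(marginal: np.ndarray, method: str = "max") -> float:
    """Modulation depth of a phase-binned marginal, in percent.

    ``method='max'``: 100 × (max − min)/max — a marginal touching zero at its
    minimum gives 100%. ``method='mean'``: 100 × (max − min)/mean.
    """
    marginal = np.asarray(marginal, float)
    valid = marginal[np.isfinite(marginal)]
    if len(valid) < 2:
        raise ValueError("need at least two phase bins")
    hi, lo = valid.max(), valid.min()
    if method == "max":
        denom = hi
    elif method == "mean":
        denom = valid.mean()
    else:
        raise ValueError(f"unknown method {method!r}")
    if denom == 0:
        raise ValueError("modulation depth undefined for an all-zero marginal")
    return 100.0 * (hi - lo) / denom


def find_series_peaks(values: np.ndarray, times: np.ndarray,
                      reference_peak_times: np.ndarray | None = None,
                      prominence_frac: float = 0.25) -> np.ndarray:
    """Peak times of a (v_rms) series by local-maximum search.

    Prominence threshold is a fraction of the interquartile range; the
    minimum spacing is half the median reference (R-R) interval when reference
    peaks are given. NaN gaps are linearly interpolated before detection.
    """
    values = np.asarray(values, float)
    times = np.asarray(times, float)
    if np.any(~np.isfinite(values)):
        good = np.isfinite(values)
        values = np.interp(times, times[good], values[good])
    q1, q3 = np.percentile(values, [25, 75])
    prominence = prominence_frac * (q3 - q1)
    distance = None
    if reference_peak_times is not None and len(reference_peak_times) > 1:
        dt = float(np.median(np.diff(times)))
        rr = float(np.median(np.diff(reference_peak_times)))
        distance = max(1, int(round(0.5 * rr / dt)))
    idx, _ = signal.find_peaks(values, prominence=prominence, distance=distance)
    return times[idx]


def delay_distribution(series_peak_times: np.ndarray, reference_peak_times: np.ndarray,
                       bin_width: float = 0.010,
                       max_delay: float | None = None) -> DelayDistribution:
    """Distribution of delays from each reference peak to the NEXT series peak.

    Reference peaks with no subsequent series peak are dropped and counted.
    The histogram is normalized to a probability density (integral 1).
    """
    series = np.sort(np.asarray(series_peak_times, float))
    refs = np.asarray(reference_peak_times, float)
    if len(series) == 0 or len(refs) == 0:
        raise ValueError("both peak series must be nonempty")
    nxt = np.searchsorted(series, refs, side="right")
    has_next = nxt < len(series)
    delays = series[nxt[has_next]] - refs[has_next]
    n_dropped = int((~has_next).sum())
    if len(delays) == 0:
        raise ValueError("no reference peak has a subsequent series peak")
    if max_delay is None:
        if len(refs) > 1:
            max_delay = float(np.median(np.diff(refs)))
        else:
            max_delay = float(delays.max()) + bin_width
    edges = np.arange(0.0, max_delay + bin_width, bin_width)
    inside = delays < edges[-1]
    density, edges = np.histogram(delays[inside], bins=edges, density=True)
    return DelayDistribution(bin_edges=edges, density=density,
                             n_pairs=int(inside.sum()),
                             n_dropped=n_dropped + int((~inside).sum()))


def power_spectrum(values: np.ndarray, rate: float,
                   min_cycles: int = 4) -> tuple[np.ndarray, np.ndarray]:
    """One-sided periodogram (density normalization) of a uniformly sampled series.

    NaN gaps are linearly interpolated first. A record shorter than
    ``min_cycles`` of the lowest resolvable frequency (i.e. fewer than
    ``2 * min_cycles`` samples) is rejected.
    """
    values = np.asarray(values, float)
    if len(values) < 2 * min_cycles:
        raise ValueError(f"series too short for a spectrum ({len(values)} samples)")
    if np.any(~np.isfinite(values)):
        idx = np.arange(len(values))
        good = np.isfinite(values)
        values = np.interp(idx, idx[good], values[good])
    freq, power = signal.periodogram(values, fs=rate, detrend="constant")
    return freq, power


def dominant_frequency(values: np.ndarray, rate: float) -> float:
    """Frequency of the largest non-DC periodogram peak, in Hz."""
    freq, power = power_spectrum(values, rate)
    power = power.copy()
    power[0] = 0.0
    return float(freq[int(np.argmax(power))])
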