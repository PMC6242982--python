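"""Rigid-translation registration of image time series to subpixel accuracy.

A time series of rigid translations (no rotation or deformation) aligns each
frame to a reference built in two passes: first against the temporal mean of
a robust frame subset, then against the mean of the first-pass registered
stack. Shift estimation uses upsampled cross-correlation (accurate to well
under 0.2 px on clean data); outlier shifts are repaired by linear
interpolation; translated frames are padded with zeros to a common shape.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from skimage.registration import phase_cross_correlation

from .io import ImageStack


class RegistrationError(RuntimeError):
    """Registration cannot be performed (e.g. a constant frame, or all outliers)."""


@dataclass
class TranslationSeries:
    """Per-frame subpixel shifts (dx, dy) in px and outlier flags."""

    dx: np.ndarray
    dy: np.ndarray
    outlier: np.ndarray

    def __post_init__(self) -> None:
        self.dx = np.asarray(self.dx, float)
        self.dy = np.asarray(self.dy, float)
        self.outlier = np.asarray(self.outlier, bool)
        if not len(self.dx) == len(self.dy) == len(self.outlier):
            raise ValueError("dx, dy and outlier must have one entry per frame")

    def __len__(self) -> int:
        return len(self.dx)


def estimate_shift(frame: np.ndarray, reference: np.ndarray,
                   upsample_factor: int = 50) -> tuple[float, float]:
    """Subpixel translation (dx, dy) that aligns ``frame`` to ``reference``.

    Applying the returned shift to ``frame`` (content moved by +dx columns,
    +dy rows) registers it with the reference.
    """
    frame = np.asarray(frame, float)
    reference = np.asarray(reference, float)
    if frame.shape != reference.shape:
        raise ValueError("frame and reference must have the same shape")
    if frame.std() == 0 or reference.std() == 0:
        raise RegistrationError("constant frame cannot be registered")
    shift, _, _ = phase_cross_correlation(reference, frame,
                                          upsample_factor=upsample_factor,
                                          normalization=None)
    dy, dx = shift
    return float(dx), float(dy)


def repair_outliers(series: TranslationSeries, threshold: float = 3.0,
                    window: int = 5) -> TranslationSeries:
    """Replace shifts that jump away from a local median by linear interpolation.

    A frame is flagged when either component deviates from the running median
    (window of ``window`` frames) by more than ``threshold`` px. Flagged
    values are linearly interpolated from the nearest valid frames; flagged
    endpoints are clamped to the nearest valid value.
    """
    if len(series) < 3:
        raise ValueError("need at least 3 frames to repair outliers")
    med_x = ndimage.median_filter(series.dx, size=window, mode="nearest")
    med_y = ndimage.median_filter(series.dy, size=window, mode="nearest")
    bad = (np.abs(series.dx - med_x) > threshold) | (np.abs(series.dy - med_y) > threshold)
    bad |= ~(np.isfinite(series.dx) & np.isfinite(series.dy))
    if bad.all():
        raise RegistrationError("every frame flagged as a registration outlier")
    if not bad.any():
        return replace(series, outlier=bad)
    idx = np.arange(len(series))
    good = ~bad
    dx = series.dx.copy()
    dy = series.dy.copy()
    dx[bad] = np.interp(idx[bad], idx[good], series.dx[good])
    dy[bad] = np.interp(idx[bad], idx[good], series.dy[good])
    return TranslationSeries(dx=dx, dy=dy, outlier=bad)


def apply_translations(stack: ImageStack, series: TranslationSeries,
                       pad_multiple: int = 15) -> ImageStack:
    """Resample every frame by its shift onto a common zero-padded canvas.

    The canvas is grown by at least the largest shift in each direction so no
    content is lost; fractional shifts use linear interpolation with zero
    fill, preserving summed intensity exactly for integer shifts. Nonzero
    pad amounts are rounded up to ``pad_multiple`` px (two 7.5-px analysis
    boxes by default) so that the velocity-binning grid, anchored at pixel
    (0, 0), stays in registry with the original pixel coordinates.
    """
    if len(series) != stack.n_frames:
        raise ValueError("series length must match frame count")
    if not (np.all(np.isfinite(series.dx)) and np.all(np.isfinite(series.dy))):
        raise ValueError("shifts must be finite")

    def _pad(amount: float) -> int:
        amount = int(np.ceil(max(amount, 0.0)))
        if amount == 0 or pad_multiple <= 1:
            return amount
        return int(np.ceil(amount / pad_multiple)) * pad_multiple

    # room BEFORE the content for negative shifts, AFTER it for positive ones
    pad_x0 = _pad(-series.dx.min())
    pad_x1 = _pad(series.dx.max())
    pad_y0 = _pad(-series.dy.min())
    pad_y1 = _pad(series.dy.max())

    data = stack.data
    squeeze = data.ndim == 3
    if squeeze:
        data = data[:, None]
    t, c, ny, nx = data.shape
    out = np.zeros((t, c, ny + pad_y0 + pad_y1, nx + pad_x0 + pad_x1),
                   dtype=float)
    for k in range(t):
        dx, dy = series.dx[k], series.dy[k]
        for ch in range(c):
            padded = np.zeros(out.shape[-2:])
            padded[pad_y0:pad_y0 + ny, pad_x0:pad_x0 + nx] = data[k, ch]
            if dx == 0 and dy == 0:
                out[k, ch] = padded
            else:
                out[k, ch] = ndimage.shift(padded, (dy, dx), order=1,
                                           mode="constant", cval=0.0)
    if squeeze:
        out = out[:, 0]
    return replace(stack, data=out)


def estimate_series(stack: ImageStack, channel: int = 0,
                    upsample_factor: int = 50,
                    outlier_threshold: float = 3.0) -> TranslationSeries:
    """Two-pass shift estimation for a whole stack.

    Pass 1 registers against the temporal mean of a robust frame subset
    (frames whose correlation with the raw mean is at least the median
    correlation); pass 2 refines against the mean of the pass-1 registered
    frames. Outliers are repaired after each pass.
    """
    frames = stack.channel(channel).data.astype(float)
    t = frames.shape[0]
    raw_mean = frames.mean(axis=0)
    if raw_mean.std() == 0:
        raise RegistrationError("stack has no spatial structure to register")

    flat = frames.reshape(t, -1)
    mu = flat.mean(axis=1, keepdims=True)
    ref_flat = raw_mean.ravel() - raw_mean.mean()
    denom = np.linalg.norm(flat - mu, axis=1) * np.linalg.norm(ref_flat)
    with np.errstate(invalid="ignore"):
        corr = (flat - mu) @ ref_flat / np.where(denom == 0, np.nan, denom)
    corr = np.nan_to_num(corr, nan=-1.0)
    subset = corr >= np.median(corr)
    reference = frames[subset].mean(axis=0)

    def _pass(ref, imgs):
        dx = np.empty(t)
        dy = np.empty(t)
        for k in range(t):
            dx[k], dy[k] = estimate_shift(imgs[k], ref, upsample_factor)
        series = TranslationSeries(dx=dx, dy=dy, outlier=np.zeros(t, bool))
        return repair_outliers(series, threshold=outlier_threshold) if t >= 3 else series

    series1 = _pass(reference, frames)
    registered = np.stack([
        ndimage.shift(frames[k], (series1.dy[k], series1.dx[k]), order=1,
                      mode="constant", cval=0.0)
        for k in range(t)
    ])
    # crop the shift-contaminated border before the refinement pass: the
    # zero-filled edge strips otherwise act as a static false feature that
    # anchors the correlation at zero shift
    b = int(np.ceil(max(np.abs(series1.dx).max(), np.abs(series1.dy).max()))) + 1
    if 2 * b < min(registered.shape[-2:]) // 2:
        registered = registered[:, b:-b, b:-b]
    series2 = _pass(registered.mean(axis=0), registered)
    # reuse `registered` frames' residual shifts; total = pass1 + pass2
    return TranslationSeries(dx=series1.dx + series2.dx,
                             dy=series1.dy + series2.dy,
                             outlier=series1.outlier | series2.outlier)


def register_stack(stack: ImageStack, channel: int = 0,
                   upsample_factor: int = 50,
                   outlier_threshold: float = 3.0) -> tuple[ImageStack, TranslationSeries]:
    """Estimate shifts on one channel and apply them to all channels."""
    series = estimate_series(stack, channel=channel,
                             upsample_factor=upsample_factor,
                             outlier_threshold=outlier_threshold)
    return apply_translations(stack, series), series
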