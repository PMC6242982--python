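"""Summary statistics of pooled velocity measurements.

Velocity measurements are binned onto a grid of 7.5 × 7.5 px boxes (bins
with fewer than 20 measurements are invalid), averaged in time to give the
velocity field and its unit-vector direction field û_avg, reduced to the
mean flow speed U (spatial mean of |time-averaged velocity|), resolved in
time as v_rms (spatial RMS of all speed measurements at each instant),
profiled against distance from the arterial wall, projected onto û_avg to
give the signed downstream component (negative = backflow), and screened by
the ≥ 80 non-stagnant-bin quality rule.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely

#: track/box stagnation threshold, µm/s
STAGNANT_SPEED = 2.0


@dataclass
class VelocityField:
    """Spatially binned time-averaged velocity statistics.

    Arrays are (ny_boxes, nx_boxes); ``valid`` marks boxes with at least the
    minimum number of measurements, and ``u_hat`` (ny, nx, 2) is the
    unit-vector field of the time-averaged velocity (NaN where undefined).
    """

    box_px: float
    mean_ux: np.ndarray
    mean_uy: np.ndarray
    mean_speed: np.ndarray
    count: np.ndarray
    valid: np.ndarray
    min_count: int

    @property
    def u_hat(self) -> np.ndarray:
        mag = np.hypot(self.mean_ux, self.mean_uy)
        with np.errstate(invalid="ignore", divide="ignore"):
            ux = np.where(self.valid & (mag > 0), self.mean_ux / mag, np.nan)
            uy = np.where(self.valid & (mag > 0), self.mean_uy / mag, np.nan)
        return np.stack([ux, uy], axis=-1)

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())


@dataclass
class VrmsSeries:
    """Spatial RMS of all speed measurements at each frame instant."""

    time: np.ndarray
    vrms: np.ndarray           # µm/s; NaN flags frames with no measurements
    count: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.vrms[np.isfinite(self.vrms)] < 0):
            raise ValueError("v_rms must be non-negative")


@dataclass
class FlowSummary:
    """Headline flow quantities for one recording."""

    mean_speed: float          # U, µm/s
    pvs_width: float | None    # L, µm
    backflow_percent: float | None
    n_valid_bins: int
    qc_pass: bool


@dataclass
class SpeedProfile:
    """Mean speed vs perpendicular distance from the arterial wall."""

    bin_centers: np.ndarray    # µm
    mean_speed: np.ndarray     # µm/s; NaN flags empty bins
    count: np.ndarray


def bin_velocities(df: pd.DataFrame, box_px: float = 7.5,
                   min_count: int = 20,
                   shape_px: tuple[int, int] | None = None) -> VelocityField:
    """Bin velocity measurements into boxes and average.

    The grid is anchored at pixel (0, 0) with boxes exactly ``box_px`` wide;
    a measurement at (x, y) falls in box (floor(x/box), floor(y/box)).
    Boxes with fewer than ``min_count`` measurements are flagged invalid and
    carry no reported average.
    """
    x = df["x_px"].to_numpy(float)
    y = df["y_px"].to_numpy(float)
    ux = df["ux_um_s"].to_numpy(float)
    uy = df["uy_um_s"].to_numpy(float)
    speed = np.hypot(ux, uy)
    ix = np.floor(x / box_px).astype(int)
    iy = np.floor(y / box_px).astype(int)
    if shape_px is not None:
        nby = int(np.ceil(shape_px[0] / box_px))
        nbx = int(np.ceil(shape_px[1] / box_px))
    else:
        nbx = int(ix.max()) + 1 if len(ix) else 1
        nby = int(iy.max()) + 1 if len(iy) else 1
    keep = (ix >= 0) & (ix < nbx) & (iy >= 0) & (iy < nby)
    ix, iy = ix[keep], iy[keep]

    def _accumulate(values):
        acc = np.zeros((nby, nbx))
        np.add.at(acc, (iy, ix), values)
        return acc

    count = _accumulate(np.ones(keep.sum()))
    sums = {name: _accumulate(vals[keep])
            for name, vals in (("ux", ux), ("uy", uy), ("speed", speed))}
    means = {}
    for name, total in sums.items():
        out = np.full((nby, nbx), np.nan)
        np.divide(total, count, out=out, where=count > 0)
        means[name] = out
    valid = count >= min_count
    for name in means:
        means[name] = np.where(valid, means[name], np.nan)
    return VelocityField(box_px=box_px, mean_ux=means["ux"], mean_uy=means["uy"],
                         mean_speed=means["speed"], count=count.astype(int),
                         valid=valid, min_count=min_count)


def mean_flow_speed(field: VelocityField, min_box_speed: float | None = None) -> float:
    """U: spatial mean over valid boxes of |time-averaged velocity| (µm/s).

    With ``min_box_speed`` set, stagnant or nearly stagnant boxes (time-
    averaged speed below it) are additionally excluded — used when computing
    condition-to-condition changes in flow speed.
    """
    mag = np.hypot(field.mean_ux, field.mean_uy)
    select = field.valid.copy()
    if min_box_speed is not None:
        select &= np.nan_to_num(field.mean_speed) >= min_box_speed
    values = mag[select]
    values = values[np.isfinite(values)]
    if len(values) == 0:
        raise ValueError("no valid boxes: mean flow speed undefined")
    return float(values.mean())


def vrms_series(df: pd.DataFrame, n_frames: int, frame_rate: float) -> VrmsSeries:
    """v_rms(t): spatial root-mean-square of all speeds at each frame.

    Frames with no measurements are flagged NaN, never zero.
    """
    frames = df["frame"].to_numpy(int)
    speed2 = df["ux_um_s"].to_numpy(float) ** 2 + df["uy_um_s"].to_numpy(float) ** 2
    sums = np.zeros(n_frames)
    counts = np.zeros(n_frames)
    keep = (frames >= 0) & (frames < n_frames)
    np.add.at(sums, frames[keep], speed2[keep])
    np.add.at(counts, frames[keep], 1)
    vrms = np.full(n_frames, np.nan)
    np.divide(sums, counts, out=vrms, where=counts > 0)
    return VrmsSeries(time=np.arange(n_frames) / frame_rate,
                      vrms=np.sqrt(vrms, where=np.isfinite(vrms), out=vrms),
                      count=counts.astype(int))


def speed_profile(df: pd.DataFrame, wall: np.ndarray,
                  bin_um: float = 2.0) -> SpeedProfile:
    """Mean speed binned by perpendicular distance from the arterial wall.

    ``wall`` is a polyline of (x, y) vertices in µm (the wall reference
    curve); the distance metric is the distance to the nearest point on it.
    Empty distance bins are NaN-flagged, not zeroed.
    """
    wall = np.asarray(wall, float)
    if wall.ndim != 2 or len(wall) < 2:
        raise ValueError("wall must be a polyline of at least two (x, y) points")
    line = shapely.LineString(wall)
    points = shapely.points(np.column_stack([df["x_um"], df["y_um"]]))
    dist = shapely.distance(points, line)
    speed = np.hypot(df["ux_um_s"].to_numpy(float), df["uy_um_s"].to_numpy(float))
    edges = np.arange(0.0, dist.max() + bin_um, bin_um)
    idx = np.clip(np.digitize(dist, edges) - 1, 0, len(edges) - 2)
    n = len(edges) - 1
    sums = np.zeros(n)
    counts = np.zeros(n)
    np.add.at(sums, idx, speed)
    np.add.at(counts, idx, 1)
    means = np.full(n, np.nan)
    np.divide(sums, counts, out=means, where=counts > 0)
    return SpeedProfile(bin_centers=0.5 * (edges[:-1] + edges[1:]),
                        mean_speed=means, count=counts.astype(int))


def downstream_component(df: pd.DataFrame, field: VelocityField) -> tuple[np.ndarray, int]:
    """Signed projection u · û_avg of each measurement; negative = backflow.

    Measurements falling in boxes without a defined û_avg are skipped (NaN)
    and counted; the skip count is returned alongside.
    """
    u_hat = field.u_hat
    nby, nbx = u_hat.shape[:2]
    ix = np.floor(df["x_px"].to_numpy(float) / field.box_px).astype(int)
    iy = np.floor(df["y_px"].to_numpy(float) / field.box_px).astype(int)
    inside = (ix >= 0) & (ix < nbx) & (iy >= 0) & (iy < nby)
    out = np.full(len(df), np.nan)
    hx = np.full(len(df), np.nan)
    hy = np.full(len(df), np.nan)
    hx[inside] = u_hat[iy[inside], ix[inside], 0]
    hy[inside] = u_hat[iy[inside], ix[inside], 1]
    out = df["ux_um_s"].to_numpy(float) * hx + df["uy_um_s"].to_numpy(float) * hy
    n_skipped = int(np.sum(~np.isfinite(out)))
    return out, n_skipped


def backflow_percent(components: np.ndarray) -> float:
    """Percent of downstream-velocity measurements that are negative.

    Zeros count as non-backflow (strictly negative measurements only);
    NaN-skipped measurements are excluded from the denominator.
    """
    comp = np.asarray(components, float)
    comp = comp[np.isfinite(comp)]
    if len(comp) == 0:
        raise ValueError("need at least one downstream component")
    return 100.0 * float(np.mean(comp < 0))


def qc_nonstagnant_bins(field: VelocityField, stagnant_mask: np.ndarray | None = None,
                        min_bins: int = 80) -> tuple[int, bool]:
    """Count valid boxes outside the stagnant mask; fail below ``min_bins``.

    A box counts as stagnant when the mask covers at least half its pixels.
    Recordings failing this rule are excluded from analysis.
    """
    valid = field.valid.copy()
    if stagnant_mask is not None:
        mask = np.asarray(stagnant_mask, bool)
        nby, nbx = valid.shape
        box = field.box_px
        for iy in range(nby):
            for ix in range(nbx):
                if not valid[iy, ix]:
                    continue
                y0, y1 = int(np.floor(iy * box)), int(np.ceil((iy + 1) * box))
                x0, x1 = int(np.floor(ix * box)), int(np.ceil((ix + 1) * box))
                patch = mask[y0:min(y1, mask.shape[0]), x0:min(x1, mask.shape[1])]
                if patch.size and patch.mean() >= 0.5:
                    valid[iy, ix] = False
    count = int(valid.sum())
    return count, count >= min_bins
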