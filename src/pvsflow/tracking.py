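"""Microsphere detection, trajectory linking and per-frame velocities.

Particles are located as intensity-weighted centroids of local maxima
(subpixel), linked frame-to-frame by greedy mutual-nearest-neighbour
assignment within a displacement gate (no gap closing: a missed detection
terminates the track, so every velocity is strictly frame-adjacent), and
differentiated to µm/s. Stagnant-particle regions are masked out of all
velocity measurements, and tracks slower than ~2 µm/s on average are
discarded as stagnant.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from skimage.feature import peak_local_max

from .io import ImageStack, TRACK_COLUMNS


@dataclass
class ParticleTrack:
    """One particle's time series of positions and velocities.

    Frames are consecutive (no gaps); velocities are central differences on
    interior frames and one-sided at the ends, in µm/s; ``mean_speed`` is the
    summed per-frame displacement divided by the number of frames tracked,
    expressed in µm/s.
    """

    track_id: int
    frames: np.ndarray
    x_px: np.ndarray
    y_px: np.ndarray
    t_s: np.ndarray | None = None
    x_um: np.ndarray | None = None
    y_um: np.ndarray | None = None
    ux_um_s: np.ndarray | None = None
    uy_um_s: np.ndarray | None = None
    mean_speed: float | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, int)
        if len(self.frames) > 1 and np.any(np.diff(self.frames) != 1):
            raise ValueError("track frames must be consecutive")

    def __len__(self) -> int:
        return len(self.frames)


@dataclass
class StagnantMask:
    """Binary exclusion mask (True = stagnant region) with its threshold."""

    mask: np.ndarray
    threshold: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, bool)


def detect_particles(frame: np.ndarray, intensity_threshold: float,
                     min_separation: int = 3, window: int = 3) -> np.ndarray:
    """Subpixel particle positions in one frame as an (N, 2) array of (x, y).

    Local maxima above the threshold, separated by at least
    ``min_separation`` px, each refined by an intensity-weighted centroid of
    the above-threshold signal in a ``(2*window+1)²`` neighbourhood.
    """
    frame = np.asarray(frame, float)
    peaks = peak_local_max(frame, min_distance=min_separation,
                           threshold_abs=intensity_threshold, exclude_border=False)
    if len(peaks) == 0:
        return np.empty((0, 2))
    ny, nx = frame.shape
    positions = []
    for row, col in peaks:
        y0, y1 = max(row - window, 0), min(row + window + 1, ny)
        x0, x1 = max(col - window, 0), min(col + window + 1, nx)
        patch = frame[y0:y1, x0:x1] - intensity_threshold
        patch = np.clip(patch, 0.0, None)
        total = patch.sum()
        if total == 0:
            positions.append((float(col), float(row)))
            continue
        ys, xs = np.mgrid[y0:y1, x0:x1]
        positions.append((float((xs * patch).sum() / total),
                          float((ys * patch).sum() / total)))
    return np.asarray(positions)


def link_tracks(detections: list[np.ndarray], max_displacement: float = 5.0,
                predictive: bool = False) -> list[ParticleTrack]:
    """Link per-frame detections into trajectories.

    Greedy assignment in order of increasing displacement (which realizes
    mutual-best matching) among candidate pairs closer than
    ``max_displacement``; ties break deterministically by track id then
    detection index. Unmatched detections start new tracks; unmatched tracks
    terminate. Every detection belongs to exactly one track.

    With ``predictive=True`` each track is matched around its linearly
    extrapolated next position (constant velocity) instead of its last
    position, which prevents identity swaps when the per-frame displacement
    approaches the inter-particle spacing — e.g. during the systolic flow
    pulse. Plain nearest-neighbour linking is equivalent only while
    displacements stay well below the spacing.
    """
    finished: list[ParticleTrack] = []
    active: list[dict] = []
    next_id = 0
    for frame_idx, dets in enumerate(detections):
        dets = np.asarray(dets, float).reshape(-1, 2)
        assigned_track = set()
        assigned_det = set()
        if active and len(dets):
            if predictive:
                last = np.array([
                    2 * trk["pos"][-1] - trk["pos"][-2] if len(trk["pos"]) > 1
                    else trk["pos"][-1]
                    for trk in active])
            else:
                last = np.array([trk["pos"][-1] for trk in active])
            tree = cKDTree(dets)
            pairs = []
            for ti, pos in enumerate(last):
                for di in tree.query_ball_point(pos, max_displacement):
                    d = float(np.hypot(*(dets[di] - pos)))
                    pairs.append((d, active[ti]["id"], ti, di))
            for d, _, ti, di in sorted(pairs):
                if ti in assigned_track or di in assigned_det:
                    continue
                assigned_track.add(ti)
                assigned_det.add(di)
                active[ti]["pos"].append(dets[di])
                active[ti]["frames"].append(frame_idx)
        still_active = []
        for ti, trk in enumerate(active):
            if ti in assigned_track:
                still_active.append(trk)
            else:
                finished.append(_to_track(trk))
        active = still_active
        for di in range(len(dets)):
            if di not in assigned_det:
                active.append({"id": next_id, "pos": [dets[di]], "frames": [frame_idx]})
                next_id += 1
    finished.extend(_to_track(trk) for trk in active)
    finished.sort(key=lambda t: t.track_id)
    return finished


def _to_track(trk: dict) -> ParticleTrack:
    pos = np.asarray(trk["pos"])
    return ParticleTrack(track_id=trk["id"], frames=np.asarray(trk["frames"]),
                         x_px=pos[:, 0], y_px=pos[:, 1])


def compute_velocities(track: ParticleTrack, frame_rate: float,
                       pixel_size: float) -> ParticleTrack:
    """Fill in times, µm positions, per-frame velocities and the mean speed.

    Central differences on interior frames, one-sided at the ends. A
    length-1 track keeps positions but carries no velocities.
    """
    track.t_s = track.frames / frame_rate
    track.x_um = track.x_px * pixel_size
    track.y_um = track.y_px * pixel_size
    if len(track) < 2:
        track.ux_um_s = track.uy_um_s = None
        track.mean_speed = None
        return track
    track.ux_um_s = np.gradient(track.x_um, track.t_s)
    track.uy_um_s = np.gradient(track.y_um, track.t_s)
    steps = np.hypot(np.diff(track.x_um), np.diff(track.y_um))
    track.mean_speed = float(steps.sum() / len(track) * frame_rate)
    return track


def make_stagnant_mask(stack: ImageStack | np.ndarray,
                       quantile_threshold: float = 0.995) -> StagnantMask:
    """Mask of stagnant (stuck-particle) regions from the time-averaged movie.

    The microsphere channel is averaged over all frames; pixels above the
    given quantile of that average are excluded from every velocity
    measurement, so stuck particles cannot bias the flow speed downward.
    A mask covering more than half the field triggers a warning (almost
    certainly a misconfigured threshold).
    """
    frames = stack.data if isinstance(stack, ImageStack) else np.asarray(stack)
    if frames.ndim != 3:
        raise ValueError("expected a single-channel (T, Y, X) stack")
    mean_img = frames.mean(axis=0)
    if mean_img.std() == 0:
        warnings.warn("time-averaged image has no contrast; stagnant mask "
                      "is meaningless", RuntimeWarning)
    threshold = float(np.quantile(mean_img, quantile_threshold))
    mask = mean_img > threshold
    frac = mask.mean()
    if frac > 0.5:
        warnings.warn(f"stagnant mask covers {frac:.0%} of the field; "
                      "check the threshold", RuntimeWarning)
    return StagnantMask(mask=mask, threshold=threshold)


def filter_slow_tracks(tracks: list[ParticleTrack],
                       min_mean_speed: float = 2.0) -> list[ParticleTrack]:
    """Drop tracks whose average speed is below the stagnation threshold (µm/s)."""
    return [t for t in tracks
            if t.mean_speed is not None and t.mean_speed >= min_mean_speed]


def tracks_to_dataframe(tracks: list[ParticleTrack]) -> pd.DataFrame:
    """Flatten tracks into one velocity measurement per (track, frame) row.

    Tracks without velocities (length 1) are omitted; columns follow the
    track-table convention used by the I/O layer.
    """
    rows = []
    for t in tracks:
        if t.ux_um_s is None:
            continue
        for i in range(len(t)):
            rows.append((t.track_id, t.frames[i], t.t_s[i],
                         t.x_px[i], t.y_px[i], t.x_um[i], t.y_um[i],
                         t.ux_um_s[i], t.uy_um_s[i]))
    return pd.DataFrame(rows, columns=TRACK_COLUMNS)


def exclude_masked(df: pd.DataFrame, mask: StagnantMask) -> pd.DataFrame:
    """Drop measurements whose (rounded) position lies in the stagnant mask."""
    if len(df) == 0:
        return df
    rows = np.clip(np.round(df["y_px"]).astype(int), 0, mask.mask.shape[0] - 1)
    cols = np.clip(np.round(df["x_px"]).astype(int), 0, mask.mask.shape[1] - 1)
    keep = ~mask.mask[rows, cols]
    return df[np.asarray(keep)].reset_index(drop=True)
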