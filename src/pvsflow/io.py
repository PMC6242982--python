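"""Image, track, physiological-trace and ground-truth file I/O.

Images travel as multi-page 16-bit TIFF (single- or two-channel),
physiological traces as CSV with the sampling rate in a header comment,
tracks as CSV/HDF5 with fixed column names, and ground truth / intermediate
results as HDF5 groups.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import h5py
import tifffile

#: column order for track tables written to CSV / HDF5
TRACK_COLUMNS = [
    "track_id", "frame", "t_s",
    "x_px", "y_px", "x_um", "y_um",
    "ux_um_s", "uy_um_s",
]


@dataclass
class ImageStack:
    """A time series of intensity images with physical calibration.

    ``data`` has shape ``(T, Y, X)`` for a single channel or
    ``(T, C, Y, X)`` for a multi-channel recording. ``pixel_size`` is in
    µm per pixel and ``frame_rate`` in Hz.
    """

    data: np.ndarray
    pixel_size: float
    frame_rate: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim not in (3, 4):
            raise ValueError("ImageStack data must be (T, Y, X) or (T, C, Y, X)")
        if self.pixel_size <= 0 or self.frame_rate <= 0:
            raise ValueError("pixel_size and frame_rate must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1] if self.data.ndim == 4 else 1

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[-2:]

    @property
    def times(self) -> np.ndarray:
        """Frame acquisition times in seconds."""
        return np.arange(self.n_frames) / self.frame_rate

    def channel(self, index: int) -> "ImageStack":
        """A single-channel view of a multi-channel stack."""
        if self.data.ndim == 3:
            if index != 0:
                raise IndexError("single-channel stack has only channel 0")
            return self
        return replace(self, data=self.data[:, index])


def write_tiff(stack: ImageStack, path) -> None:
    """Write a stack as a multi-page 16-bit TIFF.

    Multi-channel stacks are written channel-interleaved with ImageJ axis
    metadata so that they round-trip through :func:`read_tiff`.
    """
    data = np.clip(stack.data, 0, np.iinfo(np.uint16).max).astype(np.uint16)
    if data.ndim == 4:
        tifffile.imwrite(path, data, imagej=True, metadata={"axes": "TCYX"})
    else:
        tifffile.imwrite(path, data, imagej=True, metadata={"axes": "TYX"})


def read_tiff(path, pixel_size: float, frame_rate: float,
              n_channels: int | None = None) -> ImageStack:
    """Read a multi-page TIFF as an :class:`ImageStack`.

    Both dialects are accepted: a 4-D ``(T, C, Y, X)`` file, or a 3-D page
    sequence that is de-interleaved when ``n_channels`` > 1 is given.
    """
    data = tifffile.imread(path)
    data = np.asarray(data)
    if data.ndim == 2:
        data = data[None]
    if data.ndim == 3 and n_channels and n_channels > 1:
        t = data.shape[0] // n_channels
        data = data[: t * n_channels].reshape(t, n_channels, *data.shape[1:])
    return ImageStack(data=data, pixel_size=pixel_size, frame_rate=frame_rate)


def write_physio_csv(path, values: np.ndarray, rate: float, name: str = "value") -> None:
    """Write a sampled trace as CSV ``(t_s, value)`` with the rate in a header comment."""
    t = np.arange(len(values)) / rate
    with open(path, "w") as fh:
        fh.write(f"# rate_hz={rate}\n")
        fh.write(f"t_s,{name}\n")
        for ti, vi in zip(t, values):
            fh.write(f"{ti:.9g},{vi:.9g}\n")


def read_physio_csv(path) -> tuple[np.ndarray, float]:
    """Read a trace written by :func:`write_physio_csv`; returns (values, rate)."""
    with open(path) as fh:
        header = fh.readline().strip()
    if not header.startswith("# rate_hz="):
        raise ValueError(f"{path}: missing '# rate_hz=' header comment")
    rate = float(header.split("=", 1)[1])
    df = pd.read_csv(path, comment="#")
    return df.iloc[:, 1].to_numpy(float), rate


def write_tracks_csv(df: pd.DataFrame, path) -> None:
    df.loc[:, TRACK_COLUMNS].to_csv(path, index=False)


def read_tracks_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_tracks_h5(df: pd.DataFrame, path, group: str = "tracks") -> None:
    with h5py.File(path, "a") as fh:
        if group in fh:
            del fh[group]
        g = fh.create_group(group)
        for col in TRACK_COLUMNS:
            g.create_dataset(col, data=df[col].to_numpy())


def read_tracks_h5(path, group: str = "tracks") -> pd.DataFrame:
    with h5py.File(path, "r") as fh:
        g = fh[group]
        return pd.DataFrame({col: g[col][()] for col in TRACK_COLUMNS})


def write_group(path, group: str, arrays: dict, attrs: dict | None = None) -> None:
    """Write a dict of arrays (ground truth, intermediates) as an HDF5 group.

    Dataset names are the dict keys; scalar metadata goes into group attrs.
    """
    with h5py.File(path, "a") as fh:
        if group in fh:
            del fh[group]
        g = fh.create_group(group)
        for key, value in arrays.items():
            g.create_dataset(key, data=np.asarray(value))
        for key, value in (attrs or {}).items():
            g.attrs[key] = value


def read_group(path, group: str) -> tuple[dict, dict]:
    with h5py.File(path, "r") as fh:
        g = fh[group]
        arrays = {key: g[key][()] for key in g}
        attrs = dict(g.attrs)
    return arrays, attrs
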