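"""Morphometry and dimensionless characterization of perivascular flow.

PVS/artery area ratios from binary masks (fluorescence-thresholded or built
by inflating superimposed particle positions to 3 × 3 px), PVS width
perpendicular to the artery axis, and the transport numbers: Stokes–Einstein
diffusivity D = kT/6πηr, Reynolds number Re = UL/ν and Péclet number
Pe = UL/D.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Boltzmann constant, m² kg s⁻² K⁻¹ (fixed, not a parameter)
BOLTZMANN = 1.38e-23


@dataclass
class ScalingInputs:
    """Physical inputs for the dimensionless numbers, SI units.

    Defaults are water at mouse body temperature (36.8 °C): kinematic
    viscosity ν = 0.697e-6 m²/s, dynamic viscosity η = 6.93e-4 kg/(m·s),
    T = 310 K, 1 µm tracer spheres (r = 0.5e-6 m) and the measured average
    PVS width L = 4.4e-5 m. U is the mean flow speed in m/s.
    """

    U: float
    L: float = 4.4e-5
    nu: float = 0.697e-6
    T: float = 310.0
    eta: float = 6.93e-4
    r: float = 0.5e-6

    def __post_init__(self) -> None:
        for name in ("U", "L", "nu", "T", "eta", "r"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass
class DimensionlessNumbers:
    Re: float
    Pe: float
    D: float     # m²/s

    def __post_init__(self) -> None:
        if min(self.Re, self.Pe, self.D) <= 0:
            raise ValueError("Re, Pe and D must be positive")


def stokes_einstein(T: float = 310.0, eta: float = 6.93e-4,
                    r: float = 0.5e-6) -> float:
    """Diffusivity D = kT/(6πηr) of a sphere of radius r (m²/s)."""
    if min(T, eta, r) <= 0:
        raise ValueError("T, eta and r must be positive")
    return BOLTZMANN * T / (6.0 * np.pi * eta * r)


def reynolds(U: float, L: float, nu: float = 0.697e-6) -> float:
    """Re = UL/ν, inertial over viscous forces."""
    if min(U, L, nu) <= 0:
        raise ValueError("U, L and nu must be positive")
    return U * L / nu


def peclet(U: float, L: float, D: float) -> float:
    """Pe = UL/D, advective over diffusive transport."""
    if min(U, L, D) <= 0:
        raise ValueError("U, L and D must be positive")
    return U * L / D


def dimensionless_numbers(inputs: ScalingInputs) -> DimensionlessNumbers:
    """All three transport numbers from one set of physical inputs."""
    D = stokes_einstein(inputs.T, inputs.eta, inputs.r)
    return DimensionlessNumbers(Re=reynolds(inputs.U, inputs.L, inputs.nu),
                                Pe=peclet(inputs.U, inputs.L, D), D=D)


def mask_from_tracks(positions: np.ndarray, image_shape: tuple[int, int]) -> np.ndarray:
    """Binary PVS mask from superimposed particle positions.

    Subpixel (x, y) positions are rounded to the nearest pixel and each
    inflated to a 3 × 3 px region; the mask is the union of those regions
    (clipped at the image border), so its area never exceeds 9 per position.
    """
    positions = np.asarray(positions, float).reshape(-1, 2)
    ny, nx = image_shape
    mask = np.zeros((ny, nx), dtype=bool)
    if len(positions) == 0:
        return mask
    cols = np.round(positions[:, 0]).astype(int)
    rows = np.round(positions[:, 1]).astype(int)
    inside = (cols >= 0) & (cols < nx) & (rows >= 0) & (rows < ny)
    if not inside.all():
        raise ValueError("positions must lie inside the image")
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            r = np.clip(rows + dr, 0, ny - 1)
            c = np.clip(cols + dc, 0, nx - 1)
            mask[r, c] = True
    return mask


def area_ratio(pvs_mask: np.ndarray, artery_mask: np.ndarray,
               roi: np.ndarray | None = None) -> float:
    """PVS area over artery area within a region of interest.

    Any overlap between the PVS and artery masks is subtracted from the PVS
    mask first, so the ratio characterizes the lateral extent of the PVS
    beyond the artery. ``roi`` defaults to the whole image.
    """
    pvs = np.asarray(pvs_mask, bool)
    artery = np.asarray(artery_mask, bool)
    if pvs.shape != artery.shape:
        raise ValueError("masks must share a shape")
    if roi is None:
        roi = np.ones_like(artery)
    roi = np.asarray(roi, bool)
    artery_area = int((artery & roi).sum())
    if artery_area == 0:
        raise ValueError("empty artery within the ROI")
    pvs_area = int((pvs & roi & ~artery).sum())
    return pvs_area / artery_area


def pvs_width(pvs_mask: np.ndarray, axis_point: tuple[float, float],
              axis_direction: tuple[float, float],
              pixel_size: float = 1.0) -> tuple[float, tuple[float, float]]:
    """Mean PVS extent perpendicular to the artery axis, in µm.

    Pixels of the mask are split by the signed perpendicular offset from the
    axis (a line through ``axis_point`` with ``axis_direction``); on each
    side the width is the mean, over 1-px bins along the axis, of the pixel
    count in the bin (an occupancy width, robust to ragged edges). Returns
    ``(average width, (width side+, width side−))``; a side with no pixels
    contributes NaN and is excluded from the average.
    """
    mask = np.asarray(pvs_mask, bool)
    if not mask.any():
        raise ValueError("empty PVS mask")
    d = np.asarray(axis_direction, float)
    norm = np.hypot(*d)
    if norm == 0:
        raise ValueError("axis_direction must be nonzero")
    d = d / norm
    rows, cols = np.nonzero(mask)
    rel = np.column_stack([cols - axis_point[0], rows - axis_point[1]])
    along = rel @ d
    across = rel[:, 0] * (-d[1]) + rel[:, 1] * d[0]

    widths = []
    for side in (across > 0, across < 0):
        if not side.any():
            widths.append(np.nan)
            continue
        bins = np.floor(along[side]).astype(int)
        counts = np.bincount(bins - bins.min())
        widths.append(float(counts[counts > 0].mean()) * pixel_size)
    per_side = (widths[0], widths[1])
    valid = [w for w in widths if np.isfinite(w)]
    return float(np.mean(valid)), per_side
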