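"""Pseudo-radial B-scan reslicing and motion-averaged en-face images.

The optic-disc cube is resliced in the en-face plane using a polar coordinate
system with the BMO center as origin: for each angle theta a cross-section
containing the r-axis and parallel to z yields a pseudo-radial image.
Stepping theta from 0 to pi in increments of delta_theta gives pi/delta_theta
images (12 for the default 15 deg).  En-face images are averaged over a
5-slice z window to suppress speckle.

Lateral sampling uses bilinear interpolation within each z plane (the device
reslices laterally only; no z interpolation).  Coordinates follow the
voxel-center convention of :mod:`lc3d.volume_io`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .volume_io import OCTVolume

__all__ = [
    "RadialImage",
    "EnFaceImage",
    "sample_intensity",
    "extract_pseudo_radial",
    "extract_radial_set",
    "extract_enface",
]


@dataclass
class RadialImage:
    """A pseudo-radial cross-section at angle ``theta``.

    ``pixels[z, k]`` is the intensity at signed radial coordinate ``s[k]``
    (µm, negative side is the theta+pi half-axis) and depth index ``z``; the
    en-face position of column ``k`` is ``center + s[k] * (cos theta, sin
    theta)``.
    """

    theta: float
    center: tuple[float, float]
    s: np.ndarray          # signed radial coordinates, µm, symmetric about 0 before clipping
    r_spacing: float       # µm per column
    pixels: np.ndarray     # [nz, len(s)]


@dataclass
class EnFaceImage:
    """A constant-depth slice averaged over ``window`` z planes."""

    z_index: int           # effective window center after boundary clamping
    window: int
    pixels: np.ndarray     # [ny, nx]


def _check_in_extent(volume: OCTVolume, x, y):
    meta = volume.meta
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    bad = (x < 0) | (x > meta.scan_width_um) | (y < 0) | (y > meta.scan_height_um)
    if np.any(bad):
        raise ValueError(
            f"en-face point outside scan extent "
            f"[0, {meta.scan_width_um}] x [0, {meta.scan_height_um}] um"
        )
    return x, y


def _bilinear_columns(volume: OCTVolume, x, y) -> np.ndarray:
    """Bilinear sample of every z plane at en-face points (x, y) µm.

    Returns an array of shape ``[nz, len(x)]``.  Fractional indices are
    clamped to the voxel-center range, i.e. the half-voxel margin inside the
    extent is edge-padded rather than extrapolated.
    """
    meta = volume.meta
    fx = np.clip(np.asarray(x) / meta.dx - 0.5, 0.0, meta.nx - 1.0)
    fy = np.clip(np.asarray(y) / meta.dy - 0.5, 0.0, meta.ny - 1.0)
    ix0 = np.minimum(np.floor(fx).astype(int), meta.nx - 2) if meta.nx > 1 else np.zeros_like(fx, int)
    iy0 = np.minimum(np.floor(fy).astype(int), meta.ny - 2) if meta.ny > 1 else np.zeros_like(fy, int)
    wx = fx - ix0
    wy = fy - iy0
    I = volume.intensity
    return (
        (1 - wy) * ((1 - wx) * I[:, iy0, ix0] + wx * I[:, iy0, ix0 + 1])
        + wy * ((1 - wx) * I[:, iy0 + 1, ix0] + wx * I[:, iy0 + 1, ix0 + 1])
    )


def sample_intensity(volume: OCTVolume, x, y, z_index: int):
    """Bilinearly interpolated intensity at en-face point ``(x, y)`` µm in plane ``z_index``.

    No extrapolation: points outside the scan extent raise ``ValueError``.
    Accepts scalars or arrays (broadcast over points).
    """
    if not (0 <= z_index < volume.meta.nz):
        raise ValueError(f"z_index {z_index} outside [0, {volume.meta.nz})")
    scalar = np.isscalar(x) and np.isscalar(y)
    x, y = _check_in_extent(volume, x, y)
    out = _bilinear_columns(volume, np.atleast_1d(x), np.atleast_1d(y))[z_index]
    return float(out[0]) if scalar else out


def extract_pseudo_radial(
    volume: OCTVolume, center, theta: float, step_um: float | None = None
) -> RadialImage:
    """Pseudo-radial image through ``center`` (µm) at angle ``theta``.

    The signed radial grid is uniform with step ``min(dx, dy)`` by default
    and symmetric about s = 0; columns falling outside the scan extent are
    clipped away.
    """
    meta = volume.meta
    cx, cy = float(center[0]), float(center[1])
    _check_in_extent(volume, cx, cy)
    if step_um is None:
        step_um = min(meta.dx, meta.dy)
    # farthest possible |s| inside the extent: distance to the farthest corner
    corners = [(0, 0), (meta.scan_width_um, 0), (0, meta.scan_height_um),
               (meta.scan_width_um, meta.scan_height_um)]
    smax = max(math.hypot(px - cx, py - cy) for px, py in corners)
    n = int(math.floor(smax / step_um))
    s = np.arange(-n, n + 1) * step_um
    x = cx + s * math.cos(theta)
    y = cy + s * math.sin(theta)
    eps = 1e-9
    keep = (x >= -eps) & (x <= meta.scan_width_um + eps) & \
           (y >= -eps) & (y <= meta.scan_height_um + eps)
    s, x, y = s[keep], np.clip(x[keep], 0, meta.scan_width_um), np.clip(y[keep], 0, meta.scan_height_um)
    pixels = _bilinear_columns(volume, x, y)
    return RadialImage(theta=theta, center=(cx, cy), s=s, r_spacing=step_um, pixels=pixels)


def extract_radial_set(
    volume: OCTVolume, center, delta_theta: float = math.radians(15.0),
    step_um: float | None = None,
) -> list[RadialImage]:
    """The full set of pi/delta_theta pseudo-radial images (theta = 0 .. pi - dtheta)."""
    k = math.pi / delta_theta
    if abs(k - round(k)) > 1e-9 or round(k) < 1:
        raise ValueError(f"pi/delta_theta must be a positive integer, got {k}")
    return [
        extract_pseudo_radial(volume, center, i * delta_theta, step_um=step_um)
        for i in range(round(k))
    ]


def extract_enface(volume: OCTVolume, z_index: int, window_slices: int = 5) -> EnFaceImage:
    """Motion-averaged en-face image: mean of ``window_slices`` planes about ``z_index``.

    The window is always full (odd, default 5 = center plane plus 4 above and
    below); near the volume boundary the center is clamped so the full window
    fits, which keeps the averaging noise statistics uniform.
    """
    meta = volume.meta
    if window_slices < 1 or window_slices % 2 == 0:
        raise ValueError(f"window_slices must be odd and >= 1, got {window_slices}")
    if meta.nz < window_slices:
        raise ValueError(f"volume has {meta.nz} planes, fewer than window {window_slices}")
    if not (0 <= z_index < meta.nz):
        raise ValueError(f"z_index {z_index} outside [0, {meta.nz})")
    half = window_slices // 2
    c = int(np.clip(z_index, half, meta.nz - 1 - half))
    pixels = volume.intensity[c - half : c + half + 1].mean(axis=0)
    return EnFaceImage(z_index=c, window=window_slices, pixels=pixels)
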