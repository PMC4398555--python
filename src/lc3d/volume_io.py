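"""OCT volume I/O and the coordinate conventions shared by all modules.

A cube scan is stored on disk as a grayscale multi-page TIFF (one page per
depth plane) or as raw little-endian binary, with a JSON sidecar giving voxel
counts and spacings in micrometres.  In memory the intensity grid is indexed
``[z][y][x]`` — ``x`` is the A-line (fast) axis, ``y`` the B-scan axis and
``z`` depth, increasing posteriorly.  Physical coordinates are voxel-center
based: the center of voxel ``ix`` lies at ``(ix + 0.5) * dx`` µm, so the scan
occupies the extent ``[0, nx * dx]`` µm along each axis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

__all__ = [
    "VolumeMeta",
    "OCTVolume",
    "MetadataError",
    "load_volume",
    "save_volume",
]

#: device geometry of a 3 x 3 mm, 2.6 mm deep, 256-B-scan cube scan
DEFAULT_COUNTS = (256, 256, 256)
DEFAULT_EXTENT_UM = (3000.0, 3000.0, 2600.0)


class MetadataError(ValueError):
    """Volume metadata is missing or inconsistent with the pixel data.

    ``field`` names the offending metadata entry.
    """

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"{field}: {message}")


@dataclass(frozen=True)
class VolumeMeta:
    """Voxel counts and spacings (µm) of a cube scan."""

    nx: int
    ny: int
    nz: int
    dx: float
    dy: float
    dz: float

    def __post_init__(self):
        for name in ("nx", "ny", "nz"):
            n = getattr(self, name)
            if not (isinstance(n, (int, np.integer)) and n >= 2):
                raise MetadataError(name, f"voxel count must be an integer >= 2, got {n!r}")
        for name in ("dx", "dy", "dz"):
            d = getattr(self, name)
            if not (np.isfinite(d) and d > 0):
                raise MetadataError(name, f"voxel spacing must be positive and finite, got {d!r}")

    # -- derived physical extents ------------------------------------------
    @property
    def scan_width_um(self) -> float:
        return self.nx * self.dx

    @property
    def scan_height_um(self) -> float:
        return self.ny * self.dy

    @property
    def depth_um(self) -> float:
        return self.nz * self.dz

    @property
    def shape(self) -> tuple[int, int, int]:
        """Array shape in ``[z][y][x]`` order."""
        return (self.nz, self.ny, self.nx)

    @classmethod
    def default(cls) -> "VolumeMeta":
        """256³ voxels spanning 3000 × 3000 × 2600 µm."""
        nx, ny, nz = DEFAULT_COUNTS
        wx, wy, wz = DEFAULT_EXTENT_UM
        return cls(nx, ny, nz, wx / nx, wy / ny, wz / nz)

    def scaled(self, n: int) -> "VolumeMeta":
        """Same physical extent resampled to ``n`` voxels per axis."""
        return VolumeMeta(
            n, n, n, self.scan_width_um / n, self.scan_height_um / n, self.depth_um / n
        )

    # -- coordinate helpers -------------------------------------------------
    def voxel_to_um(self, index, axis: str):
        """Physical coordinate (µm) of a voxel center along ``axis`` ('x'|'y'|'z')."""
        d = {"x": self.dx, "y": self.dy, "z": self.dz}[axis]
        return (np.asarray(index) + 0.5) * d

    def um_to_voxel(self, coord, axis: str):
        """Fractional voxel index of a physical coordinate along ``axis``."""
        d = {"x": self.dx, "y": self.dy, "z": self.dz}[axis]
        return np.asarray(coord) / d - 0.5

    def to_dict(self) -> dict:
        return {
            "nx": self.nx, "ny": self.ny, "nz": self.nz,
            "dx_um": self.dx, "dy_um": self.dy, "dz_um": self.dz,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "VolumeMeta":
        for key in ("nx", "ny", "nz", "dx_um", "dy_um", "dz_um"):
            if key not in d:
                raise MetadataError(key, "missing from metadata sidecar")
        return cls(int(d["nx"]), int(d["ny"]), int(d["nz"]),
                   float(d["dx_um"]), float(d["dy_um"]), float(d["dz_um"]))


class OCTVolume:
    """A cube scan: intensity grid ``[z][y][x]`` plus physical metadata."""

    def __init__(self, meta: VolumeMeta, intensity: np.ndarray):
        intensity = np.asarray(intensity)
        if intensity.shape != meta.shape:
            raise MetadataError(
                "shape",
                f"intensity grid {intensity.shape} does not match metadata {meta.shape}",
            )
        if not np.all(np.isfinite(intensity)):
            raise ValueError("intensities must be finite")
        if np.any(intensity < 0):
            raise ValueError("intensities must be non-negative")
        self.meta = meta
        self.intensity = intensity.astype(np.float64, copy=False)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, OCTVolume)
            and self.meta == other.meta
            and np.array_equal(self.intensity, other.intensity)
        )


def _sidecar_path(path: Path, meta_path=None) -> Path:
    return Path(meta_path) if meta_path is not None else Path(path).with_suffix(".json")


def load_volume(path, meta_path=None) -> OCTVolume:
    """Read a TIFF z-stack or raw binary volume with its JSON sidecar.

    Raw binaries must be little-endian uint8/uint16 in ``[z][y][x]`` order;
    the sample width is inferred from the byte length.
    """
    path = Path(path)
    with open(_sidecar_path(path, meta_path)) as fh:
        meta = VolumeMeta.from_dict(json.load(fh))

    if path.suffix.lower() in (".tif", ".tiff"):
        data = tifffile.imread(path)
        if data.ndim == 2:  # single-page stack
            data = data[None]
        if data.shape[0] != meta.nz:
            raise MetadataError("nz", f"TIFF has {data.shape[0]} pages, metadata says {meta.nz}")
        if data.shape[1:] != (meta.ny, meta.nx):
            raise MetadataError(
                "nx/ny", f"TIFF pages are {data.shape[1:]}, metadata says {(meta.ny, meta.nx)}"
            )
    else:
        raw = path.read_bytes()
        nvox = meta.nx * meta.ny * meta.nz
        if len(raw) == nvox:
            dtype = "<u1"
        elif len(raw) == 2 * nvox:
            dtype = "<u2"
        else:
            raise MetadataError(
                "nx/ny/nz",
                f"raw file of {len(raw)} bytes matches neither uint8 nor uint16 "
                f"for {nvox} voxels",
            )
        data = np.frombuffer(raw, dtype=dtype).reshape(meta.shape)
    return OCTVolume(meta, data)


def save_volume(volume: OCTVolume, path, meta_path=None, dtype=None) -> None:
    """Write a volume as a multi-page TIFF (or raw binary) plus JSON sidecar.

    Files hold unsigned 8- or 16-bit samples; ``dtype`` defaults to the
    narrowest unsigned type that holds the (rounded) intensity range.
    ``load_volume`` round-trips the result exactly for integer intensities.
    """
    path = Path(path)
    if volume.intensity.shape != volume.meta.shape:
        raise MetadataError(
            "shape",
            f"intensity grid {volume.intensity.shape} disagrees with metadata "
            f"{volume.meta.shape}",
        )
    if dtype is None:
        dtype = np.uint8 if volume.intensity.max(initial=0) <= 255 else np.uint16
    dtype = np.dtype(dtype)
    if dtype not in (np.dtype(np.uint8), np.dtype(np.uint16)):
        raise ValueError(f"unsupported sample type {dtype}; use uint8 or uint16")
    info = np.iinfo(dtype)
    data = np.clip(np.rint(volume.intensity), info.min, info.max).astype(dtype)

    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, data, photometric="minisblack")
    else:
        path.write_bytes(data.astype(data.dtype.newbyteorder("<")).tobytes())
    with open(_sidecar_path(path, meta_path), "w") as fh:
        json.dump(volume.meta.to_dict(), fh, indent=1)
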