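import numpy as np
import pytest

from lc3d.phantom import PhantomSpec, PhantomTruth, truth_annotations
from lc3d.volume_io import OCTVolume, VolumeMeta


def quiet_spec(**kw) -> PhantomSpec:
    """64-cube phantom with all texture/noise sources off (pure geometry)."""
    kw.setdefault("pore_count", 0)
    kw.setdefault("vessel_count", 0)
    kw.setdefault("speckle_sd", 0.0)
    kw.setdefault("read_noise_sd", 0.0)
    return PhantomSpec.fast(**kw)


def truth_of(spec: PhantomSpec) -> PhantomTruth:
    center = (spec.meta.scan_width_um / 2, spec.meta.scan_height_um / 2)
    return PhantomTruth(spec=spec, center=center)


@pytest.fixture
def flat_truth() -> PhantomTruth:
    return truth_of(quiet_spec())


@pytest.fixture
def flat_annotations(flat_truth):
    return truth_annotations(flat_truth, M=24, points_per_axis=9)


@pytest.fixture
def small_volume() -> OCTVolume:
    """16-cube random integer volume for I/O round-trips."""
    meta = VolumeMeta(16, 16, 16, 10.0, 10.0, 8.0)
    rng = np.random.default_rng(7)
    return OCTVolume(meta, rng.integers(0, 256, size=meta.shape).astype(float))


def ramp_volume(nx=32, ny=32, nz=8, dx=10.0, dy=10.0, dz=8.0, field="x") -> OCTVolume:
    """Volume whose intensity is an analytic function of voxel-center coords."""
    meta = VolumeMeta(nx, ny, nz, dx, dy, dz)
    x = meta.voxel_to_um(np.arange(nx), "x")
    y = meta.voxel_to_um(np.arange(ny), "y")
    z = meta.voxel_to_um(np.arange(nz), "z")
    X, Y = np.meshgrid(x, y)
    planes = {"x": X, "y": Y, "xy": 0.3 * X + 0.7 * Y + 5.0}[field]
    data = np.broadcast_to(planes, (nz, ny, nx)).copy()
    if field == "x":
        pass
    return OCTVolume(meta, data)
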