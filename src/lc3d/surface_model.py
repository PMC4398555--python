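"""Two-pass spline reconstruction of the LC surfaces on a polar grid.

Each LC border (anterior, posterior, flank) is rebuilt from its per-axis
``(r, z)`` marks in two interpolation passes:

(a) *r-directional*: a cubic interpolating spline (not-a-knot) through the
    marks of each half-axis ``i``, giving a smooth border curve ``z_i(r)``.

(b) *theta-directional*: each curve is resampled at ``N + 1`` equally spaced
    radii ``r_ij = j * terminal_r_i / N`` (``r_i0`` at the BMO origin,
    ``r_iN`` at the terminal point), and for each fixed ``j`` the ring of
    values ``z_ij`` over ``i = 0..M-1`` is closed with ``(r_Mj, z_Mj) =
    (r_0j, z_0j)`` and interpolated by a periodic cubic spline in theta,
    yielding a closed, smooth surface around the BMO origin.

Defaults are ``M = 24`` half-axes (delta_theta = 15 deg) and ``N = 140``
radial sections.  When the innermost mark sits at ``r > 0`` (a vessel shadow
over the BMO center), the radial curve is extended linearly from its
innermost segment down to ``r = 0``; such grid nodes are flagged
``extrapolated`` and are excluded from thickness measurement unless the
reliable region vouches for them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from .annotations import AnnotationSet, BorderPolyline

__all__ = [
    "RadialCurve",
    "SurfaceGrid",
    "LCModel",
    "fit_radial_curve",
    "resample_radial",
    "fit_angular_ring",
    "build_surface",
    "build_lc_model",
    "DEFAULT_M",
    "DEFAULT_N",
]

DEFAULT_M = 24
DEFAULT_N = 140


@dataclass
class RadialCurve:
    """Interpolated border curve ``z(r)`` along one half-axis.

    Inside ``[r_min, terminal_r]`` the curve is the cubic interpolant through
    the marks; on ``[0, r_min)`` it continues linearly with the slope of the
    innermost marked segment.
    """

    axis_index: int
    r_min: float
    terminal_r: float
    _spline: CubicSpline
    _inner_slope: float

    def __call__(self, r):
        r = np.asarray(r, dtype=float)
        inner = r < self.r_min
        z = self._spline(np.clip(r, self.r_min, None))
        if np.any(inner):
            z0 = float(self._spline(self.r_min))
            z = np.where(inner, z0 + self._inner_slope * (r - self.r_min), z)
        return z if z.ndim else float(z)

    def is_extrapolated(self, r):
        return np.asarray(r, dtype=float) < self.r_min - 1e-9


@dataclass
class SurfaceGrid:
    """One reconstructed surface on the polar ``M x (N+1)`` grid.

    ``z_grid[i, j]`` is the surface depth at ``r_grid[i, j] = j *
    terminal_r[i] / N`` on axis ``i``; the per-``j`` periodic ring evaluators
    are retained for dense evaluation between the axes.
    """

    M: int
    N: int
    delta_theta: float
    terminal_r: np.ndarray        # (M,)
    r_grid: np.ndarray            # (M, N+1)
    z_grid: np.ndarray            # (M, N+1)
    extrapolated: np.ndarray      # (M, N+1) bool
    rings: list = field(repr=False, default_factory=list)       # N+1 periodic evaluators
    curves: list = field(repr=False, default_factory=list)      # M radial curves

    def theta(self, i=None) -> np.ndarray:
        idx = np.arange(self.M) if i is None else np.asarray(i)
        return idx * self.delta_theta

    def ring_values(self, j: int, theta) -> np.ndarray:
        """Dense evaluation of ring ``j`` at arbitrary angles."""
        return self.rings[j](np.mod(theta, 2 * math.pi))


@dataclass
class LCModel:
    """The 3D LC model: anterior and posterior surfaces (and optional flank)."""

    anterior: SurfaceGrid
    posterior: SurfaceGrid
    flank: SurfaceGrid | None
    bmo_center: tuple[float, float]
    delta_theta: float
    warnings: list[str] = field(default_factory=list)


def fit_radial_curve(polyline: BorderPolyline) -> RadialCurve:
    """Cubic interpolating spline (not-a-knot) through one axis's marks."""
    r, z = polyline.r_values, polyline.z_values
    if len(r) < 4:
        raise ValueError(f"axis {polyline.axis_index}: need >= 4 points, got {len(r)}")
    if np.any(np.diff(r) <= 0):
        raise ValueError(f"axis {polyline.axis_index}: duplicate or non-increasing r")
    spline = CubicSpline(r, z, bc_type="not-a-knot")
    inner_slope = (z[1] - z[0]) / (r[1] - r[0])
    return RadialCurve(
        axis_index=polyline.axis_index,
        r_min=float(r[0]),
        terminal_r=float(r[-1]),
        _spline=spline,
        _inner_slope=float(inner_slope),
    )


def resample_radial(curve: RadialCurve, N: int) -> np.ndarray:
    """Equally sectioned samples ``(r_j, z_j)``, ``r_j = j * terminal_r / N``.

    Returns an ``(N+1, 2)`` array; ``r_0 = 0`` (BMO origin) and ``r_N`` is
    the terminal point.
    """
    if N < 2:
        raise ValueError(f"N must be >= 2, got {N}")
    r = np.linspace(0.0, curve.terminal_r, N + 1)
    return np.column_stack([r, curve(r)])


def fit_angular_ring(values) -> CubicSpline:
    """Periodic cubic spline through M values at ``theta_i = i * 2 pi / M``.

    The ring is closed by identifying ``(theta_M, z_M) = (theta_0, z_0)``, so
    the evaluator satisfies ``z(0) = z(2 pi)`` with a continuous first
    derivative across the seam.
    """
    values = np.asarray(values, dtype=float)
    M = len(values)
    if M < 4:
        raise ValueError(f"need >= 4 angular samples, got {M}")
    theta = np.linspace(0.0, 2 * math.pi, M + 1)
    return CubicSpline(theta, np.append(values, values[0]), bc_type="periodic")


def build_surface(
    polylines: dict[int, BorderPolyline] | list[BorderPolyline],
    M: int = DEFAULT_M,
    N: int = DEFAULT_N,
) -> SurfaceGrid:
    """Full two-pass reconstruction of one surface from M per-axis polylines."""
    if not isinstance(polylines, dict):
        polylines = {p.axis_index: p for p in polylines}
    missing = [i for i in range(M) if i not in polylines]
    if missing:
        raise ValueError(f"missing polylines for axes {missing}")
    delta_theta = 2 * math.pi / M

    curves = [fit_radial_curve(polylines[i]) for i in range(M)]
    samples = [resample_radial(c, N) for c in curves]
    r_grid = np.stack([s[:, 0] for s in samples])
    z_grid = np.stack([s[:, 1] for s in samples])
    extrapolated = np.stack([c.is_extrapolated(r) for c, r in zip(curves, r_grid)])
    rings = [fit_angular_ring(z_grid[:, j]) for j in range(N + 1)]

    return SurfaceGrid(
        M=M, N=N, delta_theta=delta_theta,
        terminal_r=np.array([c.terminal_r for c in curves]),
        r_grid=r_grid, z_grid=z_grid, extrapolated=extrapolated,
        rings=rings, curves=curves,
    )


def build_lc_model(
    aset: AnnotationSet, M: int | None = None, N: int = DEFAULT_N
) -> LCModel:
    """Build anterior/posterior (and flank, if marked) surfaces from one annotation set.

    ``M`` defaults to the annotation set's own axis count; a mismatch is an
    error.  Nodes where the posterior surface lies anterior to the anterior
    surface (crossing grids, possible near the flank with noisy marks) are
    reported as warnings, not errors.
    """
    if M is None:
        M = aset.M
    elif M != aset.M:
        raise ValueError(f"requested M={M} but annotation set has {aset.M} axes")

    surfaces = {}
    for kind in ("anterior", "posterior"):
        polys = aset.polylines(kind)
        missing = [i for i in range(M) if i not in polys]
        if missing:
            raise ValueError(f"{kind} polylines missing for axes {missing}")
        surfaces[kind] = build_surface(polys, M=M, N=N)
    flank_polys = aset.polylines("flank")
    flank = build_surface(flank_polys, M=M, N=N) if len(flank_polys) == M else None

    warnings = []
    ant, post = surfaces["anterior"], surfaces["posterior"]
    if np.allclose(ant.terminal_r, post.terminal_r, rtol=1e-9, atol=1e-6):
        crossing = np.argwhere(post.z_grid < ant.z_grid - 1e-9)
        if len(crossing):
            warnings.append(
                f"posterior surface anterior to anterior surface at {len(crossing)} "
                f"grid node(s), first at (axis, j) = {tuple(crossing[0])}"
            )

    return LCModel(
        anterior=ant, posterior=post, flank=flank,
        bmo_center=aset.bmo.center, delta_theta=2 * math.pi / M,
        warnings=warnings,
    )
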