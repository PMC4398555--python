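"""Reliably measurable region, thickness map and average LC thickness.

The per-axis reliable marks are closed into a smooth boundary by periodic
cubic-spline interpolation in the en-face plane; extruding that cross-section
along z and intersecting it with the LC model yields the reliably measurable
region.  Thickness is measured along z (posterior minus anterior depth) at
every polar grid node inside the region, and the average LC thickness
(avgLCT) is the area-weighted mean over the region, with polar area elements
``r * dr * dtheta`` (trapezoid-corrected at the innermost and outermost
sections).  The same closed-curve machinery gives the reliable area, the BMO
area, and their ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy.interpolate import CubicSpline
from shapely.geometry import Polygon

from .annotations import ReliableBound
from .surface_model import LCModel

__all__ = [
    "ClosedCurve2D",
    "RegionMask",
    "ThicknessMap",
    "build_closed_boundary",
    "curve_area",
    "mask_polar_grid",
    "compute_thickness_map",
    "average_thickness",
    "area_ratio",
    "boundary_from_bounds",
    "boundary_from_bmo",
]

_DENSE = 4096  # parameter samples for area integrals and polygonization


@dataclass
class ClosedCurve2D:
    """A closed periodic-spline curve in the en-face plane (µm).

    Control points are interpolated by periodic cubic splines ``x(u)``,
    ``y(u)`` with ``u_k = k * 2 pi / K``, so value and first derivative are
    continuous across the seam.
    """

    control_points: np.ndarray  # (K, 2)
    _sx: CubicSpline = field(repr=False, default=None)
    _sy: CubicSpline = field(repr=False, default=None)

    def __post_init__(self):
        pts = np.asarray(self.control_points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 4:
            raise ValueError("need >= 4 control points of shape (K, 2)")
        self.control_points = pts
        u = np.linspace(0.0, 2 * math.pi, len(pts) + 1)
        self._sx = CubicSpline(u, np.append(pts[:, 0], pts[0, 0]), bc_type="periodic")
        self._sy = CubicSpline(u, np.append(pts[:, 1], pts[0, 1]), bc_type="periodic")

    def __call__(self, u):
        u = np.mod(u, 2 * math.pi)
        return np.stack([self._sx(u), self._sy(u)], axis=-1)

    def polygon(self, n: int = _DENSE) -> Polygon:
        u = np.linspace(0.0, 2 * math.pi, n, endpoint=False)
        return Polygon(self(u))

    def is_simple(self, n: int = _DENSE) -> bool:
        return self.polygon(n).is_valid

    def area_um2(self, n: int = _DENSE) -> float:
        """Enclosed area by Green's theorem, orientation-independent."""
        u = np.linspace(0.0, 2 * math.pi, n + 1)
        x, y = self._sx(u), self._sy(u)
        dx, dy = self._sx(u, 1), self._sy(u, 1)
        return abs(float(np.trapezoid(x * dy - y * dx, u)) / 2.0)

    def contains(self, x, y) -> np.ndarray:
        """Vectorized point-in-region test (boundary counts as inside)."""
        poly = self.polygon()
        shapely.prepare(poly)
        return shapely.covers(poly, shapely.points(np.column_stack(
            [np.atleast_1d(x).astype(float), np.atleast_1d(y).astype(float)]
        )))


@dataclass
class RegionMask:
    """Boolean mask over the polar surface grid plus its generating boundary."""

    mask: np.ndarray            # (M, N+1) bool
    boundary: ClosedCurve2D


@dataclass
class ThicknessMap:
    """Per-node LC thickness (µm) with reliable-region mask and area weights (µm²)."""

    thickness: np.ndarray       # (M, N+1)
    mask: RegionMask
    area_weight: np.ndarray     # (M, N+1)
    r_grid: np.ndarray
    delta_theta: float


def build_closed_boundary(points, check_simple: bool = True) -> ClosedCurve2D:
    """Periodic closed curve through per-axis en-face points (angular order)."""
    curve = ClosedCurve2D(np.asarray(points, dtype=float))
    if check_simple and not curve.is_simple():
        raise ValueError("closed boundary is self-intersecting")
    return curve


def curve_area(curve: ClosedCurve2D) -> float:
    """Enclosed area in mm² (control points are in µm)."""
    if not curve.is_simple():
        raise ValueError("cannot compute the area of a self-intersecting curve")
    return curve.area_um2() / 1e6


def boundary_from_bounds(
    bounds: list[ReliableBound] | dict[int, ReliableBound],
    center, delta_theta: float,
) -> ClosedCurve2D:
    """Reliable-region boundary through the per-axis outer reliable marks.

    Reproduces the construction of closing the intersections of the per-image
    reliable limits with the en-face plane into a periodic curve.
    """
    if not isinstance(bounds, dict):
        bounds = {b.axis_index: b for b in bounds}
    M = round(2 * math.pi / delta_theta)
    missing = [i for i in range(M) if i not in bounds]
    if missing:
        raise ValueError(f"reliable bounds missing for axes {missing}")
    cx, cy = center
    pts = [
        (cx + bounds[i].r_outer * math.cos(i * delta_theta),
         cy + bounds[i].r_outer * math.sin(i * delta_theta))
        for i in range(M)
    ]
    return build_closed_boundary(pts)


def boundary_from_bmo(aset) -> ClosedCurve2D:
    """Closed curve through the per-axis BMO edge points (for BMO area)."""
    edges = aset.bmo.edge_points
    M = aset.M
    missing = [i for i in range(M) if i not in edges]
    if missing:
        raise ValueError(f"BMO edge points missing for axes {missing}")
    cx, cy = aset.bmo.center
    pts = [
        (cx + edges[i].r * math.cos(aset.theta(i)),
         cy + edges[i].r * math.sin(aset.theta(i)))
        for i in range(M)
    ]
    return build_closed_boundary(pts)


def mask_polar_grid(
    model: LCModel,
    bounds: list[ReliableBound] | dict[int, ReliableBound],
    boundary: ClosedCurve2D,
) -> RegionMask:
    """Node-level reliable-region mask.

    Node ``(i, j)`` is reliable iff its radius lies within that axis's
    ``[r_inner, r_outer]`` interval, its en-face position falls inside the
    extruded boundary, and its anterior/posterior values are interpolated
    (not inner extrapolations across a central vessel shadow).
    """
    if not isinstance(bounds, dict):
        bounds = {b.axis_index: b for b in bounds}
    grid = model.anterior
    M, N = grid.M, grid.N
    cx, cy = model.bmo_center
    theta = grid.theta()[:, None]
    x = cx + grid.r_grid * np.cos(theta)
    y = cy + grid.r_grid * np.sin(theta)

    mask = np.zeros((M, N + 1), dtype=bool)
    for i in range(M):
        if i in bounds:
            b = bounds[i]
            mask[i] = (grid.r_grid[i] >= b.r_inner - 1e-9) & (grid.r_grid[i] <= b.r_outer + 1e-9)
    inside = boundary.contains(x.ravel(), y.ravel()).reshape(M, N + 1)
    mask &= inside
    mask &= ~model.anterior.extrapolated
    mask &= ~model.posterior.extrapolated
    return RegionMask(mask=mask, boundary=boundary)


def _polar_weights(r_grid: np.ndarray, terminal_r: np.ndarray, delta_theta: float) -> np.ndarray:
    """Exact sector-cell areas: dtheta * integral of r over each radial cell.

    Cell ``j`` spans ``[r_j - h/2, r_j + h/2]`` clipped to ``[0, terminal]``
    (half cells at j = 0 and j = N), so the weights along one axis sum to the
    circular-sector area ``dtheta * terminal^2 / 2`` exactly.
    """
    M, n = r_grid.shape
    h = (terminal_r / (n - 1))[:, None]
    lo = np.clip(r_grid - h / 2, 0.0, None)
    hi = np.minimum(r_grid + h / 2, terminal_r[:, None])
    return delta_theta * (hi**2 - lo**2) / 2.0


def compute_thickness_map(model: LCModel, mask: RegionMask) -> ThicknessMap:
    """Per-node thickness (posterior z - anterior z, along z) with area weights.

    Requires anterior and posterior grids to share terminal radii (aligned
    ``r`` grids); negative thickness at a reliable node is an error because
    it means the surfaces cross inside the region being measured.
    """
    ant, post = model.anterior, model.posterior
    if ant.M != post.M or ant.N != post.N:
        raise ValueError("anterior and posterior grids differ in M or N")
    if not np.allclose(ant.terminal_r, post.terminal_r, rtol=1e-9, atol=1e-6):
        raise ValueError(
            "anterior and posterior terminal radii differ; the polar grids are "
            "not aligned, so nodewise thickness is undefined"
        )
    thickness = post.z_grid - ant.z_grid
    bad = np.argwhere((thickness < -1e-9) & mask.mask)
    if len(bad):
        raise ValueError(
            f"negative thickness at {len(bad)} reliable node(s): "
            f"{[tuple(map(int, b)) for b in bad[:10]]}"
        )
    weights = _polar_weights(ant.r_grid, ant.terminal_r, ant.delta_theta)
    return ThicknessMap(
        thickness=thickness, mask=mask, area_weight=weights,
        r_grid=ant.r_grid, delta_theta=ant.delta_theta,
    )


def average_thickness(tmap: ThicknessMap, weighted: bool = True) -> float:
    """avgLCT (µm): area-weighted mean thickness over the reliable region.

    ``weighted=False`` gives the plain node mean for comparison (the polar
    grid over-represents the center, so the unweighted mean is biased toward
    central thickness).
    """
    m = tmap.mask.mask
    if not m.any():
        raise ValueError("reliable region is empty; no nodes to average")
    if weighted:
        w = tmap.area_weight[m]
        return float(np.sum(w * tmap.thickness[m]) / np.sum(w))
    return float(tmap.thickness[m].mean())


def area_ratio(reliable_area_mm2: float, bmo_area_mm2: float) -> float:
    """Ratio of reliably measurable area to BMO area, in percent."""
    if not bmo_area_mm2 > 0:
        raise ValueError("BMO area must be positive")
    return 100.0 * reliable_area_mm2 / bmo_area_mm2
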