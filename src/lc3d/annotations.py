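"""Data model and JSON (de)serialization for manual LC border marks.

An operator marks the anterior and posterior LC borders (and optionally the
flank) on each pseudo-radial image as ordered ``(r, z)`` points in µm, with
the BMO center as the polar origin.  Axes are indexed ``i = 0..M-1`` at
``theta_i = i * delta_theta`` counter-clockwise from +x in the en-face view;
pseudo-radial image ``k`` (``k = 0..M/2-1``) contains the two half-axes ``k``
and ``k + M/2``.  Each polyline carries at least 4 points including its two
terminals, with strictly increasing ``r``.  Per-axis reliable intervals
``[r_inner, r_outer]`` delimit the reliably measurable region, and per-axis
BMO edge points support the BMO-area computation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "PointRZ",
    "BorderPolyline",
    "ReliableBound",
    "BMOMark",
    "AnnotationSet",
    "AnnotationError",
    "load_annotations",
    "save_annotations",
    "validate_annotations",
]

SURFACES = ("anterior", "posterior", "flank")
MIN_POINTS = 4  # two terminals plus at least two interior marks


class AnnotationError(ValueError):
    """Annotation data violates the marking rules (names field and axis)."""

    def __init__(self, message: str, field: str | None = None, axis: int | None = None):
        self.field = field
        self.axis = axis
        where = "" if axis is None else f" (axis {axis})"
        super().__init__(f"{message}{where}")


@dataclass(frozen=True)
class PointRZ:
    """One marked point: radial coordinate ``r`` >= 0 and depth ``z``, both µm."""

    r: float
    z: float

    def __post_init__(self):
        if not (np.isfinite(self.r) and self.r >= 0):
            raise AnnotationError(f"r must be finite and >= 0, got {self.r!r}", field="r")
        if not np.isfinite(self.z):
            raise AnnotationError(f"z must be finite, got {self.z!r}", field="z")


@dataclass
class BorderPolyline:
    """Ordered marks along one half-axis for one surface.

    The first and last points are the terminals; ``r`` must be strictly
    increasing (non-monotone marks are an operator error, rejected outright).
    """

    axis_index: int
    surface: str
    points: list[PointRZ]

    def __post_init__(self):
        if self.surface not in SURFACES:
            raise AnnotationError(
                f"surface must be one of {SURFACES}, got {self.surface!r}",
                field="surface", axis=self.axis_index,
            )
        if len(self.points) < MIN_POINTS:
            raise AnnotationError(
                f"polyline has {len(self.points)} points; at least {MIN_POINTS} "
                "(including both terminals) are required",
                field="points", axis=self.axis_index,
            )
        r = self.r_values
        if not np.all(np.diff(r) > 0):
            raise AnnotationError(
                "r coordinates must be strictly increasing",
                field="points", axis=self.axis_index,
            )

    @property
    def r_values(self) -> np.ndarray:
        return np.array([p.r for p in self.points])

    @property
    def z_values(self) -> np.ndarray:
        return np.array([p.z for p in self.points])

    @property
    def terminal_r(self) -> float:
        """Outer terminal radius (the curve's outermost extent)."""
        return self.points[-1].r


@dataclass(frozen=True)
class ReliableBound:
    """Reliably measurable interval ``[r_inner, r_outer]`` (µm) on one axis."""

    axis_index: int
    r_inner: float
    r_outer: float

    def __post_init__(self):
        if not (0 <= self.r_inner < self.r_outer):
            raise AnnotationError(
                f"require 0 <= r_inner < r_outer, got [{self.r_inner}, {self.r_outer}]",
                field="reliable", axis=self.axis_index,
            )


@dataclass
class BMOMark:
    """BMO center (en-face µm) and one optional edge point per axis."""

    center: tuple[float, float]
    edge_points: dict[int, PointRZ] = field(default_factory=dict)


@dataclass
class AnnotationSet:
    """All manual marks for one eye."""

    bmo: BMOMark
    borders: list[BorderPolyline]
    reliable: list[ReliableBound]
    delta_theta: float  # radians

    def __post_init__(self):
        m = 2 * math.pi / self.delta_theta
        if abs(m - round(m)) > 1e-9 or round(m) < 4:
            raise AnnotationError(
                f"delta_theta must divide 2*pi into >= 4 axes, got {self.delta_theta}",
                field="delta_theta",
            )

    @property
    def M(self) -> int:
        return round(2 * math.pi / self.delta_theta)

    def theta(self, axis_index: int) -> float:
        return axis_index * self.delta_theta

    def polylines(self, surface: str) -> dict[int, BorderPolyline]:
        return {b.axis_index: b for b in self.borders if b.surface == surface}

    def reliable_by_axis(self) -> dict[int, ReliableBound]:
        return {b.axis_index: b for b in self.reliable}


# ---------------------------------------------------------------------------
# JSON schema:
# {"delta_theta_deg": 15,
#  "bmo": {"center_um": [x, y], "edges": [{"axis": i, "r_um": .., "z_um": ..}]},
#  "borders": [{"axis": i, "surface": "anterior|posterior|flank",
#               "points_um": [[r, z], ...]}],
#  "reliable": [{"axis": i, "r_inner_um": .., "r_outer_um": ..}]}
# ---------------------------------------------------------------------------

def load_annotations(path) -> AnnotationSet:
    with open(path) as fh:
        doc = json.load(fh)
    try:
        bmo_doc = doc["bmo"]
        bmo = BMOMark(
            center=(float(bmo_doc["center_um"][0]), float(bmo_doc["center_um"][1])),
            edge_points={
                int(e["axis"]): PointRZ(float(e["r_um"]), float(e["z_um"]))
                for e in bmo_doc.get("edges", [])
            },
        )
        borders = [
            BorderPolyline(
                axis_index=int(b["axis"]),
                surface=b["surface"],
                points=[PointRZ(float(r), float(z)) for r, z in b["points_um"]],
            )
            for b in doc["borders"]
        ]
        reliable = [
            ReliableBound(int(b["axis"]), float(b["r_inner_um"]), float(b["r_outer_um"]))
            for b in doc.get("reliable", [])
        ]
        delta_theta = math.radians(float(doc["delta_theta_deg"]))
    except KeyError as exc:
        raise AnnotationError(f"missing field {exc.args[0]!r}", field=str(exc.args[0]))
    return AnnotationSet(bmo=bmo, borders=borders, reliable=reliable, delta_theta=delta_theta)


def save_annotations(aset: AnnotationSet, path) -> None:
    doc = {
        "delta_theta_deg": math.degrees(aset.delta_theta),
        "bmo": {
            "center_um": list(aset.bmo.center),
            "edges": [
                {"axis": i, "r_um": p.r, "z_um": p.z}
                for i, p in sorted(aset.bmo.edge_points.items())
            ],
        },
        "borders": [
            {
                "axis": b.axis_index,
                "surface": b.surface,
                "points_um": [[p.r, p.z] for p in b.points],
            }
            for b in aset.borders
        ],
        "reliable": [
            {"axis": b.axis_index, "r_inner_um": b.r_inner, "r_outer_um": b.r_outer}
            for b in aset.reliable
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def validate_annotations(aset: AnnotationSet, meta=None) -> list[str]:
    """Check the marking rules; returns a list of violations (empty = valid).

    Checks per-axis point counts and monotone r (re-checked for sets built
    programmatically), axis-index range, anterior/posterior completeness for
    every axis that has any border, reliable bounds within the terminal
    radius, and — when ``meta`` is given — z within the imaging depth and the
    BMO center inside the scan extent.
    """
    issues: list[str] = []
    M = aset.M
    for b in aset.borders:
        if not (0 <= b.axis_index < M):
            issues.append(f"axis {b.axis_index}: index outside 0..{M - 1}")
        if len(b.points) < MIN_POINTS:
            issues.append(f"axis {b.axis_index} {b.surface}: fewer than {MIN_POINTS} points")
        if not np.all(np.diff(b.r_values) > 0):
            issues.append(f"axis {b.axis_index} {b.surface}: r not strictly increasing")
        if meta is not None:
            z = b.z_values
            if np.any(z < 0) or np.any(z > meta.depth_um):
                issues.append(f"axis {b.axis_index} {b.surface}: z outside imaging depth")

    marked_axes = {b.axis_index for b in aset.borders}
    ant, post = aset.polylines("anterior"), aset.polylines("posterior")
    for i in sorted(marked_axes):
        for name, have in (("anterior", ant), ("posterior", post)):
            if i not in have:
                issues.append(f"axis {i}: missing {name} polyline")

    for rb in aset.reliable:
        if rb.axis_index in ant and rb.axis_index in post:
            term = min(ant[rb.axis_index].terminal_r, post[rb.axis_index].terminal_r)
            if rb.r_outer > term + 1e-9:
                issues.append(
                    f"axis {rb.axis_index}: reliable r_outer {rb.r_outer:g} exceeds "
                    f"terminal radius {term:g}"
                )

    if meta is not None:
        cx, cy = aset.bmo.center
        if not (0 <= cx <= meta.scan_width_um and 0 <= cy <= meta.scan_height_um):
            issues.append("BMO center outside scan extent")
    return issues
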