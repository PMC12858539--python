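"""Vessel geometry, stenosis metrics and lesion sub-segmentation.

A vessel is represented by its centerline (arc-length parameterized, 0 at the
ostium), a lumen radius profile r(s), and a structured triangulated tube
surface whose every vertex carries its (s, angle) parameters.  All lengths are
meters internally; the public stenosis/segment interfaces report millimeters.

Lesion analysis follows the serial-CCTA convention: a proximal, non-stenotic
*reference* segment (ostium to first bifurcation) provides the normalization
denominator, and the lesion extent is tiled into contiguous 2-4 mm
sub-segments, each summarized independently.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import GeometryError, ValidationError

__all__ = [
    "VesselGeometry",
    "SegmentDefinition",
    "stenosis_metrics",
    "define_segments",
    "assign_vertices_to_segments",
]

#: segment id of the reference segment in assignment arrays
REFERENCE_ID = 0
#: segment id for vertices outside every segment
UNASSIGNED = -1


@dataclass
class VesselGeometry:
    """Centerline-parameterized tube surface with a radius profile.

    Attributes
    ----------
    centerline : (Ns, 3) float array
        Ordered centerline points, meters.
    arclength : (Ns,) float array
        Arc length s per centerline point, strictly increasing from 0.
    radius : (Ns,) float array
        Lumen radius r(s) > 0 at each centerline point.
    vertices, triangles
        Tube surface mesh; triangles index into ``vertices``.
    vertex_s, vertex_angle : (Nv,) float arrays
        Parameters of each surface vertex.
    normals : (Nv, 3) float array
        Outward unit normals of the lateral surface.
    vertex_grid : (Ns, Nc) int array
        Structured index grid: ``vertex_grid[i, k]`` is the vertex at axial
        ring i, circumferential position k.
    """

    centerline: np.ndarray
    arclength: np.ndarray
    radius: np.ndarray
    vertices: np.ndarray
    triangles: np.ndarray
    vertex_s: np.ndarray
    vertex_angle: np.ndarray
    normals: np.ndarray
    vertex_grid: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        s = np.asarray(self.arclength, dtype=float)
        if s[0] != 0.0 or np.any(np.diff(s) <= 0):
            raise GeometryError("arclength must increase strictly from 0")
        if np.any(np.asarray(self.radius) <= 0):
            raise GeometryError("radius profile must be positive everywhere")
        norms = np.linalg.norm(self.normals, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-9):
            raise GeometryError("normals must be unit length within 1e-9")
        vs = np.asarray(self.vertex_s)
        if vs.min() < -1e-12 or vs.max() > self.length + 1e-12:
            raise GeometryError("vertex s outside [0, vessel_length]")

    @property
    def length(self) -> float:
        return float(self.arclength[-1])

    @property
    def n_axial(self) -> int:
        return self.vertex_grid.shape[0]

    @property
    def n_circ(self) -> int:
        return self.vertex_grid.shape[1]

    def radius_at(self, s) -> np.ndarray | float:
        """Lumen radius at arbitrary arc length(s), linear interpolation."""
        return np.interp(s, self.arclength, self.radius)

    def ring_radii(self) -> np.ndarray:
        """Per-ring lumen radius measured from the mesh itself.

        Mean distance of each axial ring of vertices to its centerline point;
        invariant under rigid-body transforms applied consistently to
        ``vertices`` and ``centerline``.
        """
        ring_pts = self.vertices[self.vertex_grid]  # (Ns, Nc, 3)
        d = ring_pts - self.centerline[:, None, :]
        return np.linalg.norm(d, axis=2).mean(axis=1)

    def axial_tangents(self) -> np.ndarray:
        """Per-vertex unit tangent of the surface along increasing s."""
        ring_pts = self.vertices[self.vertex_grid]  # (Ns, Nc, 3)
        t = np.gradient(ring_pts, self.arclength, axis=0)
        t /= np.linalg.norm(t, axis=2, keepdims=True)
        out = np.empty_like(self.vertices)
        out[self.vertex_grid.ravel()] = t.reshape(-1, 3)
        return out

    def vertex_areas(self) -> np.ndarray:
        """Lumped per-vertex area: one third of each incident triangle."""
        tri = self.triangles
        p = self.vertices
        cross = np.cross(p[tri[:, 1]] - p[tri[:, 0]], p[tri[:, 2]] - p[tri[:, 0]])
        a = 0.5 * np.linalg.norm(cross, axis=1)
        areas = np.zeros(len(p))
        for c in range(3):
            np.add.at(areas, tri[:, c], a / 3.0)
        return areas

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "VesselGeometry":
        """Rigid-body copy (used to verify invariance of derived metrics)."""
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        return VesselGeometry(
            centerline=self.centerline @ R.T + t,
            arclength=self.arclength.copy(),
            radius=self.radius.copy(),
            vertices=self.vertices @ R.T + t,
            triangles=self.triangles.copy(),
            vertex_s=self.vertex_s.copy(),
            vertex_angle=self.vertex_angle.copy(),
            normals=self.normals @ R.T,
            vertex_grid=self.vertex_grid.copy(),
            metadata=dict(self.metadata),
        )


@dataclass
class SegmentDefinition:
    """Reference interval plus contiguous lesion sub-intervals (meters)."""

    reference: tuple[float, float]
    sub_intervals: list[tuple[float, float]]
    lesion_extent: float

    def __post_init__(self) -> None:
        a, b = self.reference
        if not a < b:
            raise ValidationError("reference interval must have positive length")
        for (s0, s1), (t0, _t1) in zip(self.sub_intervals, self.sub_intervals[1:]):
            if not math.isclose(s1, t0, rel_tol=0, abs_tol=1e-12):
                raise ValidationError("lesion sub-intervals must be contiguous")
        if self.sub_intervals:
            if b > self.sub_intervals[0][0] + 1e-12:
                raise ValidationError("reference must lie proximal to the lesion")
            total = sum(s1 - s0 for s0, s1 in self.sub_intervals)
            if not math.isclose(total, self.lesion_extent, rel_tol=0, abs_tol=1e-12):
                raise ValidationError("sub-interval lengths must sum to lesion extent")

    @property
    def n_segments(self) -> int:
        return len(self.sub_intervals)

    def to_json(self) -> str:
        return json.dumps(
            {
                "reference_m": list(self.reference),
                "sub_intervals_m": [list(iv) for iv in self.sub_intervals],
                "lesion_extent_m": self.lesion_extent,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "SegmentDefinition":
        d = json.loads(text)
        return cls(
            reference=tuple(d["reference_m"]),
            sub_intervals=[tuple(iv) for iv in d["sub_intervals_m"]],
            lesion_extent=d["lesion_extent_m"],
        )


def stenosis_metrics(
    geom: VesselGeometry,
    proximal_reference_s: float,
    epsilon: float = 0.05,
) -> dict:
    """Diameter/area stenosis degree, MLA, lesion length and MLA location.

    Stenosis degree (area) = (proximal normal lumen area - minimum lumen
    area) / proximal normal lumen area x 100; the diameter version
    (1 - d_min/d_ref) x 100 is reported alongside.  The lesion extent is the
    contiguous region around the minimum where the mesh-measured radius falls
    below (1 - epsilon) of the reference radius.

    Radii are measured from the surface mesh (ring mean distance to the
    centerline), so the result is invariant to rigid-body transforms.

    Returns a dict with keys ``DS_diameter`` and ``DS_area`` (percent),
    ``MLA`` (mm^2), ``lesion_length`` (mm), ``s_MLA`` (m),
    ``lesion_extent`` ((s_start, s_end) in m) and ``no_narrowing`` flag.
    """
    s = geom.arclength
    r = geom.ring_radii()
    if not 0 <= proximal_reference_s <= geom.length:
        raise ValidationError("proximal_reference_s outside the vessel")
    r_ref = float(np.interp(proximal_reference_s, s, r))
    a_ref = math.pi * r_ref**2
    if a_ref <= 0:
        raise GeometryError("reference lumen area must be positive")

    i_min = int(np.argmin(r))
    r_min = float(r[i_min])
    s_mla = float(s[i_min])
    mla = math.pi * r_min**2

    ds_area = (a_ref - mla) / a_ref * 100.0
    ds_diam = (1.0 - r_min / r_ref) * 100.0

    below = r < (1.0 - epsilon) * r_ref
    no_narrowing = not bool(below[i_min])
    if no_narrowing:
        lesion_length = 0.0
        extent = (s_mla, s_mla)
    else:
        i0 = i_min
        while i0 > 0 and below[i0 - 1]:
            i0 -= 1
        i1 = i_min
        while i1 < len(s) - 1 and below[i1 + 1]:
            i1 += 1
        extent = (float(s[i0]), float(s[i1]))
        lesion_length = (extent[1] - extent[0]) * 1e3

    return {
        "DS_diameter": ds_diam,
        "DS_area": ds_area,
        "MLA": mla * 1e6,
        "lesion_length": lesion_length,
        "s_MLA": s_mla,
        "lesion_extent": extent,
        "no_narrowing": no_narrowing,
    }


def define_segments(
    geom: VesselGeometry,
    lesion_extent: tuple[float, float],
    sub_length: float,
    reference: tuple[float, float] | None = None,
    merge_small_remainder: bool = False,
) -> SegmentDefinition:
    """Tile the lesion extent into contiguous sub-segments of ``sub_length``.

    Parameters
    ----------
    lesion_extent : (s_start, s_end), meters
    sub_length : meters, must lie in the 2-4 mm window
    reference : optional (s_a, s_b), meters
        Proximal healthy reference interval.  Defaults to [0, lesion start),
        i.e. ostium to the beginning of the narrowing (a stand-in for "ostium
        to first bifurcation" on single-branch vessels).
    merge_small_remainder : bool
        If True, a trailing remainder shorter than 1 mm is merged into the
        previous sub-segment instead of forming its own short segment.

    The number of sub-segments defaults to ceil(extent / sub_length); the
    most distal segment carries any remainder.
    """
    if not 2e-3 - 1e-12 <= sub_length <= 4e-3 + 1e-12:
        raise ValidationError("sub_length must lie in [2, 4] mm")
    s0, s1 = lesion_extent
    if not (0 <= s0 < s1 <= geom.length + 1e-12):
        raise ValidationError("lesion extent must lie within the vessel")
    extent = s1 - s0

    if reference is None:
        reference = (0.0, s0)
    ra, rb = reference
    if not (0 <= ra < rb <= s0 + 1e-12):
        raise GeometryError(
            "vessel too short to host a proximal reference before the lesion"
        )

    n = math.ceil(extent / sub_length - 1e-12)
    bounds = [s0 + i * sub_length for i in range(n)] + [s1]
    if merge_small_remainder and n >= 2 and (bounds[-1] - bounds[-2]) < 1e-3:
        del bounds[-2]
    intervals = list(zip(bounds[:-1], bounds[1:]))
    return SegmentDefinition(
        reference=(ra, rb), sub_intervals=intervals, lesion_extent=extent
    )


def assign_vertices_to_segments(s_values: np.ndarray, segdef: SegmentDefinition) -> np.ndarray:
    """Map arc-length positions to segment ids.

    Returns an int array: ``UNASSIGNED`` (-1) outside every segment,
    ``REFERENCE_ID`` (0) inside the reference interval, and 1..K for the K
    lesion sub-segments.  Intervals are half-open [start, end): a position
    exactly on an interior boundary belongs to the distal-side segment (the
    very last lesion boundary is closed so the lesion end point is kept).
    """
    s = np.asarray(s_values, dtype=float)
    out = np.full(s.shape, UNASSIGNED, dtype=int)
    ra, rb = segdef.reference
    out[(s >= ra) & (s < rb)] = REFERENCE_ID
    for k, (a, b) in enumerate(segdef.sub_intervals, start=1):
        if k == len(segdef.sub_intervals):
            mask = (s >= a) & (s <= b)
        else:
            mask = (s >= a) & (s < b)
        out[mask] = k
    return out
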