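"""Streamline endpoint-to-surface assignment and per-triangle count fields.

Each streamline contributes its two termination points.  Every termination
point is assigned to the globally nearest mesh vertex across both
hemispheres (Euclidean distance, KD-tree accelerated; ties broken towards
the lowest vertex id with left-hemisphere vertices indexed before right).
Per-vertex endpoint counts are then summarised per triangle as the median
of the triangle's three vertex counts, displayed as ``log(1 + n)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.spatial import cKDTree

from .errors import ValidationError

__all__ = [
    "CorticalSurface",
    "Tractogram",
    "EndpointAssignment",
    "TriangleCountField",
    "assign_endpoints",
    "triangle_counts",
    "triangle_median_counts",
    "hemisphere_coverage",
]

_HEMISPHERES = ("left", "right")

# Relative slack used when deciding that two nearest-vertex distances tie.
_TIE_RTOL = 1e-9


@dataclass(frozen=True)
class CorticalSurface:
    """Triangulated cortical (mid-)surface of one hemisphere, in millimetres.

    Parameters
    ----------
    vertices : (V, 3) float array
        Vertex coordinates in RAS millimetres.
    triangles : (T, 3) int array
        Vertex-index triples; each triangle must reference three distinct
        existing vertices.
    hemisphere : {"left", "right"}
    """

    vertices: np.ndarray
    triangles: np.ndarray
    hemisphere: str

    def __post_init__(self):
        vertices = np.asarray(self.vertices, dtype=float)
        triangles = np.asarray(self.triangles, dtype=np.int64)
        if self.hemisphere not in _HEMISPHERES:
            raise ValidationError(
                f"hemisphere must be one of {_HEMISPHERES}, got {self.hemisphere!r}"
            )
        if vertices.ndim != 2 or vertices.shape[1] != 3 or len(vertices) < 3:
            raise ValidationError("vertices must be an (V>=3, 3) array")
        if not np.all(np.isfinite(vertices)):
            raise ValidationError("vertex coordinates must be finite")
        if triangles.ndim != 2 or triangles.shape[1] != 3:
            raise ValidationError("triangles must be a (T, 3) index array")
        if triangles.size:
            if triangles.min() < 0 or triangles.max() >= len(vertices):
                raise ValidationError("triangle indices reference missing vertices")
            degenerate = (
                (triangles[:, 0] == triangles[:, 1])
                | (triangles[:, 0] == triangles[:, 2])
                | (triangles[:, 1] == triangles[:, 2])
            )
            if degenerate.any():
                bad = int(np.flatnonzero(degenerate)[0])
                raise ValidationError(
                    f"degenerate triangle {bad}: repeated vertex index"
                )
        object.__setattr__(self, "vertices", vertices)
        object.__setattr__(self, "triangles", triangles)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    def triangle_areas(self) -> np.ndarray:
        """Area of each triangle in mm^2."""
        a, b, c = (self.vertices[self.triangles[:, i]] for i in range(3))
        return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)

    def translated(self, offset) -> "CorticalSurface":
        return CorticalSurface(
            self.vertices + np.asarray(offset, dtype=float),
            self.triangles,
            self.hemisphere,
        )


@dataclass(frozen=True)
class Tractogram:
    """A set of streamlines; each an ordered (k >= 2, 3) polyline in mm."""

    streamlines: Sequence[np.ndarray]

    def __post_init__(self):
        checked = []
        for i, sl in enumerate(self.streamlines):
            arr = np.asarray(sl, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 3 or len(arr) < 2:
                raise ValidationError(
                    f"streamline {i} must be a (k>=2, 3) point array"
                )
            if not np.all(np.isfinite(arr)):
                raise ValidationError(f"streamline {i} has non-finite coordinates")
            checked.append(arr)
        object.__setattr__(self, "streamlines", tuple(checked))

    @property
    def n_streamlines(self) -> int:
        return len(self.streamlines)

    def endpoints(self) -> np.ndarray:
        """All termination points, shape (2N, 3).

        Ordered ``[s0 first, s0 last, s1 first, s1 last, ...]`` so that
        endpoint ``e`` belongs to streamline ``e // 2``, end ``e % 2``.
        """
        if not self.streamlines:
            return np.empty((0, 3))
        return np.concatenate(
            [np.stack([sl[0], sl[-1]]) for sl in self.streamlines]
        )

    def translated(self, offset) -> "Tractogram":
        off = np.asarray(offset, dtype=float)
        return Tractogram([sl + off for sl in self.streamlines])


@dataclass(frozen=True)
class EndpointAssignment:
    """Nearest-vertex assignment of every streamline termination point.

    Vertices are globally indexed with the left hemisphere first:
    global ids ``[0, n_left)`` are left vertices, ``[n_left, n_total)``
    right vertices.  ``vertex == -1`` marks an endpoint left unassigned by
    the optional distance cap.
    """

    streamline_index: np.ndarray  # (2N,) int
    end: np.ndarray  # (2N,) int in {0, 1}: first/last point
    vertex: np.ndarray  # (2N,) int global vertex id, -1 if unassigned
    distance: np.ndarray  # (2N,) float mm
    vertex_counts: np.ndarray  # (n_total_vertices,) int
    n_left_vertices: int

    @property
    def n_endpoints(self) -> int:
        return len(self.vertex)

    @property
    def n_assigned(self) -> int:
        return int(np.sum(self.vertex >= 0))

    def counts_for(self, surface: CorticalSurface) -> np.ndarray:
        """Per-vertex endpoint counts restricted to one hemisphere."""
        n_right = len(self.vertex_counts) - self.n_left_vertices
        if surface.hemisphere == "left":
            counts = self.vertex_counts[: self.n_left_vertices]
        else:
            counts = self.vertex_counts[self.n_left_vertices:]
            if len(counts) != n_right:  # pragma: no cover - defensive
                raise ValidationError("inconsistent hemisphere split")
        if len(counts) != surface.n_vertices:
            raise ValidationError(
                "surface vertex count does not match the assignment "
                f"({surface.n_vertices} vs {len(counts)})"
            )
        return counts


@dataclass(frozen=True)
class TriangleCountField:
    """Per-triangle endpoint-count summary for one hemisphere.

    ``n`` is the median of the triangle's three vertex counts (an integer,
    since the median of three integers is one of them); ``any_hit`` is
    True where any of the three vertex counts is >= 1.  The display value
    is ``log(1 + n)`` (natural log), zero iff ``n`` is zero.
    """

    n: np.ndarray  # (T,) int
    any_hit: np.ndarray  # (T,) bool
    hemisphere: str

    @property
    def n_triangles(self) -> int:
        return len(self.n)

    def display(self) -> np.ndarray:
        return np.log1p(self.n.astype(float))


def _as_surface_pair(surfaces) -> Tuple[CorticalSurface, CorticalSurface]:
    try:
        left, right = surfaces
    except (TypeError, ValueError) as exc:
        raise ValidationError("surfaces must be a (left, right) pair") from exc
    if left.hemisphere != "left" or right.hemisphere != "right":
        raise ValidationError("surface pair must be ordered (left, right)")
    return left, right


def assign_endpoints(
    tractogram: Tractogram,
    surfaces: Tuple[CorticalSurface, CorticalSurface],
    max_distance_mm: Optional[float] = None,
) -> EndpointAssignment:
    """Assign every streamline termination point to its nearest mesh vertex.

    Both endpoints of every streamline are assigned independently to the
    closest vertex (shortest Euclidean distance) across the two
    hemisphere meshes.  Distance ties go to the lowest global vertex id,
    with left-hemisphere vertices enumerated before right.  Endpoints
    farther than ``max_distance_mm`` (if given) are recorded as
    unassigned and excluded from the per-vertex counts.

    Returns an :class:`EndpointAssignment`; an empty tractogram yields an
    empty assignment (not an error), while an empty surface raises
    :class:`~transcallosal.errors.ValidationError`.
    """
    left, right = _as_surface_pair(surfaces)
    if left.n_triangles == 0 or right.n_triangles == 0:
        raise ValidationError("cannot assign endpoints against an empty surface")
    all_vertices = np.vstack([left.vertices, right.vertices])
    n_total = len(all_vertices)

    points = tractogram.endpoints()
    n_pts = len(points)
    if n_pts == 0:
        return EndpointAssignment(
            streamline_index=np.empty(0, dtype=np.int64),
            end=np.empty(0, dtype=np.int64),
            vertex=np.empty(0, dtype=np.int64),
            distance=np.empty(0, dtype=float),
            vertex_counts=np.zeros(n_total, dtype=np.int64),
            n_left_vertices=left.n_vertices,
        )

    tree = cKDTree(all_vertices)
    k = min(8, n_total)
    dist, idx = tree.query(points, k=k)
    if k == 1:
        dist = dist[:, None]
        idx = idx[:, None]
    # Break exact (and numerically near-exact) distance ties towards the
    # lowest global vertex id.
    tol = _TIE_RTOL * (1.0 + dist[:, :1])
    tied = dist <= dist[:, :1] + tol
    candidate = np.where(tied, idx, n_total)
    vertex = candidate.min(axis=1).astype(np.int64)
    distance = dist[:, 0]

    if max_distance_mm is not None:
        vertex = np.where(distance <= max_distance_mm, vertex, -1)

    counts = np.bincount(vertex[vertex >= 0], minlength=n_total).astype(np.int64)
    e = np.arange(n_pts)
    return EndpointAssignment(
        streamline_index=e // 2,
        end=e % 2,
        vertex=vertex,
        distance=distance,
        vertex_counts=counts,
        n_left_vertices=left.n_vertices,
    )


def triangle_median_counts(
    vertex_counts: np.ndarray, triangles: np.ndarray
) -> np.ndarray:
    """Median of the three per-vertex counts of each triangle (exact int)."""
    tri = np.asarray(vertex_counts)[np.asarray(triangles)]
    return np.sort(tri, axis=1)[:, 1]


def triangle_counts(
    assignment: EndpointAssignment, surface: CorticalSurface
) -> TriangleCountField:
    """Summarise per-vertex endpoint counts as a per-triangle field.

    ``n`` for each triangle is the median of its three vertex counts;
    the display value is ``log(1 + n)``.
    """
    counts = assignment.counts_for(surface)
    tri = counts[surface.triangles]
    return TriangleCountField(
        n=np.sort(tri, axis=1)[:, 1],
        any_hit=(tri >= 1).any(axis=1),
        hemisphere=surface.hemisphere,
    )


def hemisphere_coverage(
    fieldf: TriangleCountField,
    surface: CorticalSurface,
    area_weighted: bool = False,
    rule: str = "median",
) -> float:
    """Fraction of a hemisphere's surface involved in callosal connectivity.

    A triangle is involved when its median count ``n >= 1`` (default
    ``rule="median"``, matching the displayed field) or when any of its
    three vertex counts is >= 1 (``rule="any"``).  With ``area_weighted``
    the involved-triangle area is divided by total area instead of the
    triangle count.
    """
    if surface.n_triangles == 0:
        raise ValidationError("coverage is undefined for a zero-triangle surface")
    if fieldf.n_triangles != surface.n_triangles:
        raise ValidationError("field was not built for this surface")
    involved = _involved_mask(fieldf, rule)
    if area_weighted:
        areas = surface.triangle_areas()
        total = areas.sum()
        if total <= 0:
            raise ValidationError("surface has zero total area")
        return float(areas[involved].sum() / total)
    return float(involved.mean())


def _involved_mask(fieldf: TriangleCountField, rule: str) -> np.ndarray:
    if rule == "median":
        return fieldf.n >= 1
    if rule == "any":
        return fieldf.any_hit
    raise ValidationError(f"unknown involvement rule {rule!r}")
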