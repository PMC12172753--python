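"""Triangulated cortical surfaces with unit-sphere registrations.

A :class:`TriSurface` bundles what the mapping pipeline needs from a
FreeSurfer-style cortical reconstruction: vertex coordinates (RAS,
millimetres), triangle faces (0-based), per-vertex signed curvature,
per-vertex atlas labels, and — optionally — a unit-sphere registration
(one unit vector per vertex) that provides cross-subject correspondence.

Warping a subject vertex to a template vertex searches the template
sphere for the vertex minimising great-circle distance plus a curvature
mismatch penalty, so that gyral/sulcal geometry (curvature sign) is
respected rather than raw angular proximity alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "TriSurface",
    "StimulationEvent",
    "VertexMapping",
    "project_event_to_vertex",
    "project_point_to_vertex",
    "mask_to_region",
    "warp_vertex",
    "warp_vertices",
    "warp_events",
]


class SurfaceError(ValueError):
    """Invalid surface data or an operation applied to an unusable surface."""


@dataclass
class TriSurface:
    """Triangulated cortical mesh with curvature, labels and sphere registration.

    Parameters
    ----------
    vertices : (N, 3) float array
        Vertex coordinates in RAS millimetres.
    faces : (M, 3) int array
        0-based triangle vertex indices.
    curvature : (N,) float array
        Signed curvature per vertex (dimensionless; sign encodes gyrus/sulcus).
    atlas_labels : (N,) str array
        Atlas label per vertex (e.g. ``"precentral L"``).
    sphere : (N, 3) float array, optional
        Unit-sphere registration; every row must have unit norm within 1e-6.
    """

    vertices: np.ndarray
    faces: np.ndarray
    curvature: np.ndarray
    atlas_labels: np.ndarray
    sphere: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        self.curvature = np.asarray(self.curvature, dtype=float)
        self.atlas_labels = np.asarray(self.atlas_labels)
        if self.sphere is not None:
            self.sphere = np.asarray(self.sphere, dtype=float)
        self.validate()

    # -- validation ------------------------------------------------------

    def validate(self) -> None:
        n = len(self.vertices)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise SurfaceError("vertices must be an (N, 3) array")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise SurfaceError("faces must be an (M, 3) array")
        if len(self.faces) and (self.faces.min() < 0 or self.faces.max() >= n):
            raise SurfaceError("face indices out of range [0, N)")
        if self.curvature.shape != (n,):
            raise SurfaceError("curvature must have one value per vertex")
        if self.atlas_labels.shape != (n,):
            raise SurfaceError("atlas_labels must have one label per vertex")
        if len(self.faces):
            areas = self.face_areas()
            if np.any(areas <= 0.0):
                raise SurfaceError("mesh contains degenerate (zero-area) triangles")
        if self.sphere is not None:
            if self.sphere.shape != (n, 3):
                raise SurfaceError("sphere registration must be (N, 3)")
            norms = np.linalg.norm(self.sphere, axis=1)
            if np.any(np.abs(norms - 1.0) > 1e-6):
                raise SurfaceError("sphere registration rows must be unit vectors")

    # -- geometry --------------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def face_areas(self) -> np.ndarray:
        """Geometric triangle areas (mm^2) via the cross product."""
        v = self.vertices
        a, b, c = v[self.faces[:, 0]], v[self.faces[:, 1]], v[self.faces[:, 2]]
        return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)

    def total_area(self) -> float:
        return float(self.face_areas().sum())

    def edges(self) -> np.ndarray:
        """Unique undirected edges as an (E, 2) index array."""
        e = np.vstack(
            [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
        )
        e.sort(axis=1)
        return np.unique(e, axis=0)

    def mean_edge_length(self) -> float:
        e = self.edges()
        d = np.linalg.norm(self.vertices[e[:, 0]] - self.vertices[e[:, 1]], axis=1)
        return float(d.mean())

    def zscored_curvature(self) -> np.ndarray:
        """Curvature standardised over the surface (zeros if constant)."""
        c = self.curvature
        sd = c.std()
        if sd == 0.0:
            return np.zeros_like(c)
        return (c - c.mean()) / sd

    def with_sphere(self, sphere: np.ndarray) -> "TriSurface":
        return replace(self, sphere=np.asarray(sphere, dtype=float))


@dataclass
class StimulationEvent:
    """One TMS pulse: coil position/orientation, intensity condition, time."""

    event_id: int
    time_s: float
    coil_position: np.ndarray
    coil_orientation: np.ndarray
    intensity_condition: str

    def __post_init__(self) -> None:
        self.coil_position = np.asarray(self.coil_position, dtype=float)
        self.coil_orientation = np.asarray(self.coil_orientation, dtype=float)
        if self.coil_position.shape != (3,):
            raise ValueError("coil_position must be a 3-vector")
        if abs(np.linalg.norm(self.coil_orientation) - 1.0) > 1e-6:
            raise ValueError("coil_orientation must be a unit vector")


@dataclass
class VertexMapping:
    """Subject-to-template vertex correspondence with per-pair cost."""

    source_vertices: np.ndarray
    target_vertices: np.ndarray
    cost: np.ndarray

    def __post_init__(self) -> None:
        self.source_vertices = np.asarray(self.source_vertices, dtype=np.int64)
        self.target_vertices = np.asarray(self.target_vertices, dtype=np.int64)
        self.cost = np.asarray(self.cost, dtype=float)
        if np.any(self.cost < 0):
            raise ValueError("mapping cost must be non-negative")


# -- projection and masking ---------------------------------------------


def project_point_to_vertex(point: np.ndarray, surface: TriSurface) -> int:
    """Index of the vertex nearest (Euclidean) to ``point``; ties -> lowest index."""
    if surface.n_vertices == 0:
        raise SurfaceError("cannot project onto an empty surface")
    d2 = np.sum((surface.vertices - np.asarray(point, dtype=float)) ** 2, axis=1)
    return int(np.argmin(d2))  # argmin returns the first (lowest) index on ties


def project_event_to_vertex(event: StimulationEvent, surface: TriSurface) -> int:
    """Project a stimulation event's coil position to the nearest mesh vertex.

    Coil orientation is deliberately ignored: the coil's focal point is
    what is registered to the cortical surface, and orientation effects
    on the induced field are outside this pipeline's scope.
    """
    return project_point_to_vertex(event.coil_position, surface)


def mask_to_region(
    vertex_indices: Sequence[int] | np.ndarray,
    surface: TriSurface,
    region: str = "precentral L",
    enabled: bool = True,
) -> np.ndarray:
    """Retain the vertex indices whose atlas label equals ``region``.

    Order is preserved. ``enabled=False`` disables masking (the
    no-M1-constraint analysis variant) and returns the input unchanged.
    An unknown region (no vertex carries it) yields an empty result with
    a warning rather than an error.
    """
    idx = np.asarray(vertex_indices, dtype=np.int64)
    if not enabled:
        return idx
    if region not in surface.atlas_labels:
        import warnings

        warnings.warn(f"region {region!r} labels no vertex on this surface")
    keep = surface.atlas_labels[idx] == region
    return idx[keep]


# -- warping -------------------------------------------------------------


def _require_registration(surface: TriSurface, name: str) -> None:
    if surface.sphere is None:
        raise SurfaceError(f"{name} surface has no sphere registration")


def warp_vertices(
    source_vertices: Sequence[int] | np.ndarray,
    subject: TriSurface,
    template: TriSurface,
    lambda_curv: float = 1.0,
) -> VertexMapping:
    """Warp subject vertices to template vertices on the registration spheres.

    For each source vertex s the target is

        argmin_t  arccos(clip(s_sph . t_sph, -1, 1)) + lambda_curv * |c_s - c_t|

    over all template vertices t, where ``s_sph``/``t_sph`` are the
    unit-sphere registration coordinates and ``c`` are curvatures
    z-scored within each surface (so the two cost terms are both
    dimensionless and comparable). Ties go to the lowest template index.
    """
    _require_registration(subject, "subject")
    _require_registration(template, "template")
    src = np.asarray(source_vertices, dtype=np.int64)
    s_sph = subject.sphere[src]  # (k, 3)
    t_sph = template.sphere  # (N, 3)
    ang = np.arccos(np.clip(s_sph @ t_sph.T, -1.0, 1.0))  # (k, N)
    cost = ang
    if lambda_curv != 0.0:
        c_s = subject.zscored_curvature()[src][:, None]
        c_t = template.zscored_curvature()[None, :]
        cost = ang + lambda_curv * np.abs(c_s - c_t)
    tgt = np.argmin(cost, axis=1)
    best = cost[np.arange(len(src)), tgt]
    return VertexMapping(src, tgt, best)


def warp_vertex(
    source_vertex: int,
    subject: TriSurface,
    template: TriSurface,
    lambda_curv: float = 1.0,
) -> int:
    """Warp a single subject vertex; see :func:`warp_vertices`."""
    mapping = warp_vertices([source_vertex], subject, template, lambda_curv)
    return int(mapping.target_vertices[0])


def warp_events(
    stim_vertices: Sequence[int] | np.ndarray,
    amplitudes: Sequence[float] | np.ndarray,
    subject: TriSurface,
    template: TriSurface,
    lambda_curv: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Warp per-event subject vertices to the template, carrying MEP amplitudes.

    Returns ``(template_vertices, amplitudes)``; amplitudes pass through
    unchanged (the warp moves locations, never weights).
    """
    stim_vertices = np.asarray(stim_vertices, dtype=np.int64)
    amplitudes = np.asarray(amplitudes, dtype=float)
    if stim_vertices.shape != amplitudes.shape:
        raise ValueError("stim_vertices and amplitudes must align")
    if len(stim_vertices) == 0:
        return stim_vertices, amplitudes
    mapping = warp_vertices(stim_vertices, subject, template, lambda_curv)
    return mapping.target_vertices, amplitudes.copy()
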