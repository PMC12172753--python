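"""MEP-weighted excitability maps and their metrics.

A muscle's cortical representation is held as an :class:`ExcitabilityMap`:
a subset W = {(v_i, MEP_i)} of template vertices carrying interpolated
MEP weights. Three metrics quantify each map:

* centroid — the MEP-weighted mean vertex position,

      C(W) = (sum_i MEP_i * v_i) / (sum_i MEP_i),

* size — the MEP-weighted surface area. For each triangle k whose three
  vertices all belong to the map, with edge lengths l_1..l_3 and
  semi-perimeter L_k = (l_1 + l_2 + l_3)/2, Heron's formula gives the
  geometric area and the mean vertex weight MEP_bar_k scales it:

      ||W|| = sum_k MEP_bar_k * sqrt(L_k (L_k - l_1)(L_k - l_2)(L_k - l_3)),

* overlap — for muscles k and l on the same template,

      O_kl = ||W_k  intersect  W_l|| / ||W_k  union  W_l||,

  a Jaccard-style index in [0, 1] evaluated over triangle sets.

Interpolation from stimulation vertices to map vertices uses
inverse-distance weighting along geodesic (shortest edge-path) distances
within a cutoff radius; stimulation vertices keep their own amplitude
exactly.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from .surface import TriSurface
from .synthetic import FOREARM_MUSCLES, HAND_MUSCLES

__all__ = [
    "ExcitabilityMap",
    "AreaMetrics",
    "interpolate_to_vertices",
    "centroid",
    "area_size",
    "overlap",
    "pair_grouping",
    "SYNERGISTIC_PAIRS",
]


class MapError(ValueError):
    pass


class EmptyMapError(MapError):
    pass


class UndefinedMetricError(MapError):
    pass


@dataclass
class ExcitabilityMap:
    """A muscle's cortical representation: vertices with MEP weights."""

    surface: TriSurface
    vertex_ids: np.ndarray
    mep: np.ndarray
    muscle_label: str = ""
    intensity_condition: str = ""

    def __post_init__(self) -> None:
        self.vertex_ids = np.asarray(self.vertex_ids, dtype=np.int64)
        self.mep = np.asarray(self.mep, dtype=float)
        if self.vertex_ids.shape != self.mep.shape:
            raise MapError("vertex_ids and mep must align")
        if len(np.unique(self.vertex_ids)) != len(self.vertex_ids):
            raise MapError("vertex_ids must be unique")
        if np.any(self.mep < 0):
            raise MapError("MEP weights must be non-negative")

    def __len__(self) -> int:
        return len(self.vertex_ids)

    def complete_faces(self) -> np.ndarray:
        """Indices of surface faces whose three vertices all lie in the map."""
        member = np.zeros(self.surface.n_vertices, dtype=bool)
        member[self.vertex_ids] = True
        return np.flatnonzero(member[self.surface.faces].all(axis=1))

    def vertex_weights_full(self) -> np.ndarray:
        """Per-surface-vertex weights, zero outside the map."""
        w = np.zeros(self.surface.n_vertices)
        w[self.vertex_ids] = self.mep
        return w

    def max_normalized(self) -> "ExcitabilityMap":
        """Weights divided by their maximum (display / weighted-overlap scaling)."""
        m = self.mep.max() if len(self.mep) else 0.0
        mep = self.mep / m if m > 0 else self.mep.copy()
        return ExcitabilityMap(
            self.surface, self.vertex_ids.copy(), mep, self.muscle_label, self.intensity_condition
        )


@dataclass
class AreaMetrics:
    centroid: np.ndarray
    size: float

    def __post_init__(self) -> None:
        if self.size < 0:
            raise MapError("size must be non-negative")


# -- interpolation ---------------------------------------------------------


def _edge_graph(surface: TriSurface) -> csr_matrix:
    e = surface.edges()
    w = np.linalg.norm(surface.vertices[e[:, 0]] - surface.vertices[e[:, 1]], axis=1)
    n = surface.n_vertices
    rows = np.concatenate([e[:, 0], e[:, 1]])
    cols = np.concatenate([e[:, 1], e[:, 0]])
    return csr_matrix((np.concatenate([w, w]), (rows, cols)), shape=(n, n))


def interpolate_to_vertices(
    stim_vertices: np.ndarray,
    amplitudes: np.ndarray,
    surface: TriSurface,
    radius_mm: float = 5.0,
    muscle_label: str = "",
    intensity_condition: str = "",
) -> ExcitabilityMap:
    """Spread stimulation amplitudes to nearby vertices by geodesic IDW.

    Every vertex within geodesic (shortest edge-path) distance
    ``radius_mm`` of at least one stimulation vertex receives the
    inverse-distance-weighted mean of those amplitudes; a stimulation
    vertex receives its own amplitude exactly (the mean, when several
    pulses hit the same vertex). Vertices beyond the radius are excluded.
    """
    stim_vertices = np.asarray(stim_vertices, dtype=np.int64)
    amplitudes = np.asarray(amplitudes, dtype=float)
    if len(stim_vertices) == 0:
        raise EmptyMapError("no stimulation points to interpolate")
    if radius_mm <= 0:
        raise MapError("radius_mm must be positive")
    uniq, inv = np.unique(stim_vertices, return_inverse=True)
    # mean amplitude per unique stimulation vertex
    sums = np.zeros(len(uniq))
    counts = np.zeros(len(uniq))
    np.add.at(sums, inv, amplitudes)
    np.add.at(counts, inv, 1.0)
    stim_amp = sums / counts
    graph = _edge_graph(surface)
    dist = dijkstra(graph, directed=False, indices=uniq, limit=radius_mm)
    within = dist <= radius_mm  # (n_stim, N)
    covered = np.flatnonzero(within.any(axis=0))
    values = np.empty(len(covered))
    for out_i, v in enumerate(covered):
        d = dist[:, v]
        m = within[:, v]
        if np.any(d[m] == 0.0):
            values[out_i] = stim_amp[d == 0.0][0]
        else:
            w = 1.0 / d[m]
            values[out_i] = np.sum(w * stim_amp[m]) / np.sum(w)
    return ExcitabilityMap(surface, covered, values, muscle_label, intensity_condition)


# -- metrics ---------------------------------------------------------------


def centroid(emap: ExcitabilityMap) -> np.ndarray:
    """MEP-weighted mean position of the map's vertices."""
    total = emap.mep.sum()
    if total <= 0:
        raise UndefinedMetricError("centroid undefined for all-zero weights")
    v = emap.surface.vertices[emap.vertex_ids]
    return (emap.mep[:, None] * v).sum(axis=0) / total


def _heron_areas(surface: TriSurface, faces: np.ndarray) -> np.ndarray:
    v = surface.vertices
    tri = surface.faces[faces]
    l1 = np.linalg.norm(v[tri[:, 0]] - v[tri[:, 1]], axis=1)
    l2 = np.linalg.norm(v[tri[:, 1]] - v[tri[:, 2]], axis=1)
    l3 = np.linalg.norm(v[tri[:, 2]] - v[tri[:, 0]], axis=1)
    s = 0.5 * (l1 + l2 + l3)
    rad = s * (s - l1) * (s - l2) * (s - l3)
    return np.sqrt(np.clip(rad, 0.0, None))  # clip guards float-negative radicands


def _weighted_size(surface: TriSurface, faces: np.ndarray, weights_full: np.ndarray) -> float:
    if len(faces) == 0:
        return 0.0
    areas = _heron_areas(surface, faces)
    mean_w = weights_full[surface.faces[faces]].mean(axis=1)
    return float(np.sum(mean_w * areas))


def area_size(emap: ExcitabilityMap) -> float:
    """MEP-weighted area over the map's complete triangles (Heron formula).

    With unit weights this reduces to the geometric surface area. A map
    containing no complete triangle has size 0 (with a warning).
    """
    faces = emap.complete_faces()
    if len(faces) == 0:
        warnings.warn("map contains no complete triangle; size is 0")
        return 0.0
    return _weighted_size(emap.surface, faces, emap.vertex_weights_full())


def metrics(emap: ExcitabilityMap) -> AreaMetrics:
    return AreaMetrics(centroid(emap), area_size(emap))


def overlap(map_k: ExcitabilityMap, map_l: ExcitabilityMap, mode: str = "geometric") -> float:
    """Jaccard-style overlap of two maps on a shared template.

    Triangle sets: the intersection holds triangles complete in both
    maps, the union those complete in at least one. ``mode="geometric"``
    weights every triangle 1 (area Jaccard index). ``mode="weighted"``
    max-normalises each map's weights, then weights an intersection
    triangle by the mean of the two muscles' mean-vertex weights and a
    union-only triangle by the weight of the map that contains it.
    """
    if map_k.surface is not map_l.surface:
        raise MapError("maps must live on the same template surface")
    surface = map_k.surface
    fk = set(map_k.complete_faces().tolist())
    fl = set(map_l.complete_faces().tolist())
    inter = np.array(sorted(fk & fl), dtype=np.int64)
    union = np.array(sorted(fk | fl), dtype=np.int64)
    if len(union) == 0:
        raise UndefinedMetricError("overlap undefined: empty union")
    if mode == "geometric":
        inter_size = float(_heron_areas(surface, inter).sum()) if len(inter) else 0.0
        union_size = float(_heron_areas(surface, union).sum())
    elif mode == "weighted":
        wk = map_k.max_normalized().vertex_weights_full()
        wl = map_l.max_normalized().vertex_weights_full()
        tri_wk = wk[surface.faces].mean(axis=1)
        tri_wl = wl[surface.faces].mean(axis=1)
        in_k = np.zeros(surface.n_faces, dtype=bool)
        in_k[list(fk)] = True
        in_l = np.zeros(surface.n_faces, dtype=bool)
        in_l[list(fl)] = True
        tri_w = np.where(
            in_k & in_l, 0.5 * (tri_wk + tri_wl), np.where(in_k, tri_wk, tri_wl)
        )
        areas_union = _heron_areas(surface, union)
        union_size = float(np.sum(tri_w[union] * areas_union))
        inter_size = (
            float(np.sum(tri_w[inter] * _heron_areas(surface, inter))) if len(inter) else 0.0
        )
    else:
        raise MapError(f"unknown overlap mode {mode!r}")
    if union_size <= 0:
        raise UndefinedMetricError("overlap undefined: zero-size union")
    return inter_size / union_size


# -- muscle-pair grouping --------------------------------------------------

# Synergistic pairs (unordered): thumb-side hand muscles, the forearm
# extensor and flexor couples, and the extrinsic finger muscles (EDC, FDS)
# paired with every hand muscle.
SYNERGISTIC_PAIRS = frozenset(
    frozenset(p)
    for p in [
        ("FDI", "APB"),
        ("FDI", "FPB"),
        ("APB", "FPB"),
        ("EDC", "ECR"),
        ("FDS", "FCR"),
    ]
    + [(fm, hm) for fm in ("EDC", "FDS") for hm in ("FDI", "APB", "FPB", "ADM")]
)


def _group_of(a: str, b: str) -> str:
    ha, hb = a in HAND_MUSCLES, b in HAND_MUSCLES
    if ha and hb:
        return "hand-hand"
    if not ha and not hb:
        return "forearm-forearm"
    return "hand-forearm"


def pair_grouping(muscles: tuple[str, ...] = HAND_MUSCLES + FOREARM_MUSCLES) -> pd.DataFrame:
    """All unordered muscle pairs with group and synergy labels.

    Eight canonical muscles yield 28 pairs partitioned 6 / 16 / 6 into
    hand-hand / hand-forearm / forearm-forearm.
    """
    known = set(HAND_MUSCLES) | set(FOREARM_MUSCLES)
    unknown = [m for m in muscles if m not in known]
    if unknown:
        raise MapError(f"unknown muscle labels: {unknown}")
    rows = [
        {
            "muscle_k": a,
            "muscle_l": b,
            "pair_group": _group_of(a, b),
            "synergistic": frozenset((a, b)) in SYNERGISTIC_PAIRS,
        }
        for a, b in itertools.combinations(muscles, 2)
    ]
    return pd.DataFrame(rows)
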