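"""Triangle meshes, vertex overlays and lesion labels.

All subjects in a study live on one shared template mesh: overlays and
labels index its vertices, so geometry utilities (vertex areas, geodesic
distance, one-ring adjacency) are computed once per mesh and cached.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import dijkstra

from .errors import GeometryError

__all__ = [
    "TriangleMesh",
    "VertexOverlay",
    "LesionLabel",
    "IntensityVolume",
    "vertex_areas",
    "geodesic_distance",
]


class TriangleMesh:
    """A triangulated surface: vertices in mm, faces as vertex-index triples.

    Parameters
    ----------
    vertices : (N, 3) float array
    faces : (M, 3) int array
    normals : optional (N, 3) float array of outward unit normals; computed
        on demand (area-weighted incident-face average) when not given.
    """

    def __init__(self, vertices, faces, normals=None):
        vertices = np.ascontiguousarray(vertices, dtype=np.float64)
        faces = np.ascontiguousarray(faces, dtype=np.int64)
        if vertices.ndim != 2 or vertices.shape[1] != 3:
            raise GeometryError("vertices must be an (N, 3) array")
        if faces.ndim != 2 or faces.shape[1] != 3:
            raise GeometryError("faces must be an (M, 3) array")
        if not np.isfinite(vertices).all():
            raise GeometryError("vertex coordinates must be finite")
        n = len(vertices)
        if faces.size and (faces.min() < 0 or faces.max() >= n):
            raise GeometryError("face indices out of range")
        if faces.size:
            a, b, c = faces[:, 0], faces[:, 1], faces[:, 2]
            if np.any((a == b) | (b == c) | (a == c)):
                raise GeometryError("degenerate face (repeated vertex index)")
        self.vertices = vertices
        self.faces = faces
        self._normals = None if normals is None else np.asarray(normals, float)
        self._cache: dict = {}
        self._check_edge_manifold()

    # -- basic properties -------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def _check_edge_manifold(self) -> None:
        if not self.n_faces:
            return
        e = np.sort(
            self.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1
        )
        _, counts = np.unique(e, axis=0, return_counts=True)
        if counts.max() > 2:
            raise GeometryError("an edge is shared by more than two faces")

    @property
    def edges(self) -> np.ndarray:
        """Unique undirected edges, (E, 2) with first index the smaller."""
        if "edges" not in self._cache:
            e = np.sort(
                self.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1
            )
            self._cache["edges"] = np.unique(e, axis=0)
        return self._cache["edges"]

    @property
    def face_areas(self) -> np.ndarray:
        if "face_areas" not in self._cache:
            v = self.vertices
            f = self.faces
            cross = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
            self._cache["face_areas"] = 0.5 * np.linalg.norm(cross, axis=1)
        return self._cache["face_areas"]

    @property
    def vertex_areas(self) -> np.ndarray:
        """Barycentric vertex areas: one third of incident triangle areas."""
        if "vertex_areas" not in self._cache:
            va = np.zeros(self.n_vertices)
            np.add.at(va, self.faces.ravel(),
                      np.repeat(self.face_areas / 3.0, 3))
            self._cache["vertex_areas"] = va
        return self._cache["vertex_areas"]

    @property
    def total_area(self) -> float:
        return float(self.face_areas.sum())

    @property
    def normals(self) -> np.ndarray:
        """Outward unit vertex normals (area-weighted face-normal average)."""
        if self._normals is None:
            v, f = self.vertices, self.faces
            fn = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
            vn = np.zeros_like(v)
            for k in range(3):
                np.add.at(vn, f[:, k], fn)
            norm = np.linalg.norm(vn, axis=1, keepdims=True)
            with np.errstate(invalid="ignore", divide="ignore"):
                vn = np.where(norm > 0, vn / norm, np.nan)
            self._normals = vn
        return self._normals

    @property
    def adjacency(self) -> sparse.csr_matrix:
        """Unweighted symmetric vertex adjacency (1 on one-ring edges)."""
        if "adjacency" not in self._cache:
            e = self.edges
            n = self.n_vertices
            data = np.ones(2 * len(e))
            rows = np.concatenate([e[:, 0], e[:, 1]])
            cols = np.concatenate([e[:, 1], e[:, 0]])
            self._cache["adjacency"] = sparse.csr_matrix(
                (data, (rows, cols)), shape=(n, n)
            )
        return self._cache["adjacency"]

    @property
    def edge_graph(self) -> sparse.csr_matrix:
        """Graph for geodesic Dijkstra: one-ring edges plus two-ring chords.

        Chords between second-ring neighbours (Euclidean length) cut the
        metrication error of pure edge-path Dijkstra from ~15% to a few
        percent while keeping the computation deterministic and sparse.
        """
        if "edge_graph" not in self._cache:
            n = self.n_vertices
            adj = self.adjacency
            two_ring = (adj @ adj).tocoo()
            mask = two_ring.row < two_ring.col
            pairs = np.column_stack([two_ring.row[mask], two_ring.col[mask]])
            e = np.unique(np.vstack([self.edges, pairs]), axis=0)
            lengths = np.linalg.norm(
                self.vertices[e[:, 0]] - self.vertices[e[:, 1]], axis=1
            )
            rows = np.concatenate([e[:, 0], e[:, 1]])
            cols = np.concatenate([e[:, 1], e[:, 0]])
            data = np.concatenate([lengths, lengths])
            self._cache["edge_graph"] = sparse.csr_matrix(
                (data, (rows, cols)), shape=(n, n)
            )
        return self._cache["edge_graph"]

    def neighbors(self, index: int) -> np.ndarray:
        return self.adjacency[index].indices

    @property
    def bbox_diagonal(self) -> float:
        return float(
            np.linalg.norm(self.vertices.max(0) - self.vertices.min(0))
        )


@dataclass
class VertexOverlay:
    """One scalar per mesh vertex; NaN marks a missing value.

    ``measure_name`` uses the field's usual tokens: thickness, gwc, lgi,
    sulc, curv, jacobian — or any other string for ad-hoc overlays.
    """

    measure_name: str
    values: np.ndarray
    units: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1:
            raise GeometryError("overlay values must be a 1-D array")

    @property
    def n_vertices(self) -> int:
        return len(self.values)

    @property
    def missing(self) -> np.ndarray:
        return ~np.isfinite(self.values)

    def with_values(self, values: np.ndarray) -> "VertexOverlay":
        return VertexOverlay(self.measure_name, values, self.units)


@dataclass
class LesionLabel:
    """A set of labelled vertices (a traced, projected or synthetic lesion)."""

    vertex_indices: np.ndarray
    source: str = "manual_tracing"

    def __post_init__(self):
        idx = np.asarray(sorted(set(np.asarray(self.vertex_indices).astype(int).tolist())),
                         dtype=np.int64)
        self.vertex_indices = idx

    def __len__(self) -> int:
        return len(self.vertex_indices)

    def as_set(self) -> set:
        return set(self.vertex_indices.tolist())

    def mask(self, n_vertices: int) -> np.ndarray:
        m = np.zeros(n_vertices, dtype=bool)
        m[self.vertex_indices] = True
        return m

    def area(self, mesh: TriangleMesh) -> float:
        return float(mesh.vertex_areas[self.vertex_indices].sum())


@dataclass
class IntensityVolume:
    """A 3-D scalar image with an affine from voxel indices to surface mm."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim != 3:
            raise GeometryError("volume must be 3-D")
        if self.affine.shape != (4, 4) or abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise GeometryError("affine must be an invertible 4x4 matrix")

    def voxel_to_mm(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.atleast_2d(ijk)
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def mm_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.atleast_2d(xyz)
        inv = np.linalg.inv(self.affine)
        return xyz @ inv[:3, :3].T + inv[:3, 3]


def vertex_areas(mesh: TriangleMesh) -> VertexOverlay:
    """Barycentric vertex areas in mm² (sum equals total surface area)."""
    return VertexOverlay("vertex_area", mesh.vertex_areas.copy(), units="mm^2")


def geodesic_distance(mesh: TriangleMesh, sources: Iterable[int]) -> VertexOverlay:
    """Dijkstra edge-graph distance (mm) from every vertex to the nearest source.

    An upper bound on the true polyhedral geodesic; infinite on vertices
    unreachable from every source.
    """
    src = np.asarray(sorted(set(int(s) for s in sources)), dtype=np.int64)
    if src.size == 0:
        raise ValueError("sources must be a nonempty set of vertex indices")
    if src.min() < 0 or src.max() >= mesh.n_vertices:
        raise ValueError("source vertex index out of range")
    d = dijkstra(mesh.edge_graph, directed=False, indices=src, min_only=True)
    return VertexOverlay("geodesic_distance", d, units="mm")
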