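"""Triangulated planar surface meshes.

A regular triangulated grid stands in for the cortical surface. It provides
the two geometric ingredients the dispersion/cluster stage needs: a
per-vertex area (so an areal minimum cluster-size threshold, e.g. 200 mm²,
is meaningful) and an edge adjacency (so suprathreshold vertices can be
grouped into connected components). No folded anatomy is modelled.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

__all__ = ["MeshTopology", "build_mesh", "contiguous_patch"]


@dataclass(frozen=True)
class MeshTopology:
    """Triangle mesh with per-vertex areas and edge adjacency.

    Attributes
    ----------
    n_vertices : int
        Number of vertices.
    faces : ndarray of shape (n_faces, 3)
        Vertex indices of each triangle.
    vertex_area : ndarray of shape (n_vertices,)
        Area in mm² assigned to each vertex: one third of the summed area
        of its incident triangles (so vertex areas sum to the surface area).
    adjacency : scipy.sparse.csr_matrix
        Symmetric, irreflexive vertex-vertex adjacency from shared triangle
        edges.
    coords : ndarray of shape (n_vertices, 2)
        Planar vertex coordinates in mm (kept for pattern planting and
        block parcellation; not part of the topological contract).
    """

    n_vertices: int
    faces: np.ndarray
    vertex_area: np.ndarray
    adjacency: sparse.csr_matrix = field(repr=False)
    coords: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.n_vertices < 3:
            raise ValueError("a triangle mesh needs at least 3 vertices")
        if np.any(self.vertex_area <= 0):
            raise ValueError("vertex areas must be strictly positive")
        adj = self.adjacency
        if (adj != adj.T).nnz != 0:
            raise ValueError("adjacency must be symmetric")
        if adj.diagonal().any():
            raise ValueError("adjacency must be irreflexive")
        used = np.zeros(self.n_vertices, dtype=bool)
        used[self.faces.ravel()] = True
        if not used.all():
            raise ValueError("every vertex must belong to at least one triangle")

    @property
    def total_area(self) -> float:
        """Total surface area in mm² (equals the summed triangle areas)."""
        return float(self.vertex_area.sum())

    def neighbors(self, v: int) -> np.ndarray:
        """Indices of vertices sharing a triangle edge with ``v``."""
        a = self.adjacency
        return a.indices[a.indptr[v] : a.indptr[v + 1]]

    # -- serialization ----------------------------------------------------

    def to_json(self, path) -> None:
        payload = {
            "n_vertices": int(self.n_vertices),
            "faces": self.faces.tolist(),
            "vertex_area": self.vertex_area.tolist(),
            "coords": self.coords.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "MeshTopology":
        with open(path) as fh:
            payload = json.load(fh)
        faces = np.asarray(payload["faces"], dtype=np.int64)
        coords = np.asarray(payload["coords"], dtype=float)
        return cls(
            n_vertices=int(payload["n_vertices"]),
            faces=faces,
            vertex_area=np.asarray(payload["vertex_area"], dtype=float),
            adjacency=_adjacency_from_faces(int(payload["n_vertices"]), faces),
            coords=coords,
        )


def _adjacency_from_faces(n_vertices: int, faces: np.ndarray) -> sparse.csr_matrix:
    i = np.concatenate([faces[:, 0], faces[:, 1], faces[:, 2]])
    j = np.concatenate([faces[:, 1], faces[:, 2], faces[:, 0]])
    data = np.ones(i.size, dtype=np.int8)
    adj = sparse.coo_matrix((data, (i, j)), shape=(n_vertices, n_vertices))
    adj = adj + adj.T
    adj.data[:] = 1
    adj = sparse.csr_matrix(adj)
    adj.setdiag(0)
    adj.eliminate_zeros()
    return adj


def build_mesh(n_rows: int, n_cols: int, edge_length_mm: float = 1.0) -> MeshTopology:
    """Build a regular triangulated planar grid.

    Each grid cell is split into two triangles along a consistent diagonal,
    so interior vertices have exactly 6 neighbors. Total area equals
    ``(n_rows - 1) * (n_cols - 1) * edge_length_mm**2``.

    Parameters
    ----------
    n_rows, n_cols : int
        Grid dimensions in vertices; both must be >= 2.
    edge_length_mm : float
        Grid spacing in mm; must be positive.
    """
    if n_rows < 2 or n_cols < 2:
        raise ValueError("n_rows and n_cols must both be >= 2")
    if edge_length_mm <= 0:
        raise ValueError("edge_length_mm must be positive")

    rr, cc = np.meshgrid(np.arange(n_rows), np.arange(n_cols), indexing="ij")
    coords = np.column_stack([cc.ravel(), rr.ravel()]).astype(float) * edge_length_mm
    n_vertices = n_rows * n_cols

    faces = []
    for r in range(n_rows - 1):
        for c in range(n_cols - 1):
            v00 = r * n_cols + c
            v01 = v00 + 1
            v10 = v00 + n_cols
            v11 = v10 + 1
            # diagonal v01 -- v10 in every cell
            faces.append((v00, v01, v10))
            faces.append((v01, v11, v10))
    faces = np.asarray(faces, dtype=np.int64)

    # triangle areas via the 2-D cross product (all equal for a regular grid,
    # but computed generally)
    p0, p1, p2 = coords[faces[:, 0]], coords[faces[:, 1]], coords[faces[:, 2]]
    d1, d2 = p1 - p0, p2 - p0
    tri_area = 0.5 * np.abs(d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0])
    vertex_area = np.zeros(n_vertices)
    for k in range(3):
        np.add.at(vertex_area, faces[:, k], tri_area / 3.0)

    return MeshTopology(
        n_vertices=n_vertices,
        faces=faces,
        vertex_area=vertex_area,
        adjacency=_adjacency_from_faces(n_vertices, faces),
        coords=coords,
    )


def contiguous_patch(mesh: MeshTopology, seed_vertex: int, n_patch: int) -> np.ndarray:
    """Grow a connected patch of ``n_patch`` vertices by breadth-first search.

    Used to plant contiguous high-dispersion hotspots; ties at the BFS
    frontier are broken by vertex index for determinism.
    """
    if not 0 <= seed_vertex < mesh.n_vertices:
        raise ValueError("seed_vertex out of range")
    if not 1 <= n_patch <= mesh.n_vertices:
        raise ValueError("n_patch out of range")
    visited = np.zeros(mesh.n_vertices, dtype=bool)
    order = []
    frontier = [seed_vertex]
    visited[seed_vertex] = True
    while frontier and len(order) < n_patch:
        nxt = []
        for v in frontier:
            if len(order) >= n_patch:
                break
            order.append(v)
            for u in mesh.neighbors(v):
                if not visited[u]:
                    visited[u] = True
                    nxt.append(u)
        frontier = sorted(nxt)
    return np.asarray(sorted(order[:n_patch]), dtype=np.int64)
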