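"""Triangle adjacency graph and geodesic distances on the mesh surface.

Two triangles are adjacent when they share at least one vertex; edges are
weighted by the Euclidean centroid-to-centroid length in nm.  Vertex-sharing
(rather than edge-sharing only) adjacency gives denser connectivity, so
geodesic radii depend less on triangulation quality.  Geodesic distance
between triangles in different connected components is infinite.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components, dijkstra

from .io import SurfaceMesh, compute_triangle_geometry

__all__ = ["MeshGraph", "build_mesh_graph", "boundary_distance"]


class MeshGraph:
    """Weighted triangle-adjacency graph with geodesic queries.

    Attributes
    ----------
    adjacency : csr_matrix (nt, nt)
        Symmetric; weights are centroid distances (nm).
    component_id : (nt,) int array
        Connected-component label per triangle.
    """

    def __init__(self, adjacency: sp.csr_matrix, component_id: np.ndarray):
        self.adjacency = adjacency
        self.component_id = component_id

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    def geodesic_from(self, sources, limit: float = np.inf,
                      min_only: bool = False) -> np.ndarray:
        """Shortest-path distances from ``sources``.

        With ``min_only`` the result is the (nt,) minimum over all sources;
        otherwise one row per source.  ``limit`` truncates the search:
        distances beyond it come back as inf.
        """
        sources = np.atleast_1d(np.asarray(sources, dtype=int))
        return dijkstra(self.adjacency, directed=False, indices=sources,
                        limit=limit, min_only=min_only)

    def neighbors_within(self, radius: float, chunk: int = 512):
        """Yield (source_indices, dense distance block) for all triangles.

        Distances beyond ``radius`` are inf.  Chunked so the dense block
        never exceeds ``chunk`` rows.
        """
        n = self.n_nodes
        for start in range(0, n, chunk):
            idx = np.arange(start, min(start + chunk, n))
            dist = dijkstra(self.adjacency, directed=False, indices=idx,
                            limit=radius)
            yield idx, dist


def build_mesh_graph(mesh: SurfaceMesh) -> MeshGraph:
    """Build the vertex-sharing triangle adjacency graph.

    Degenerate (zero-area) triangles keep their node so indices stay aligned,
    but are left isolated.
    """
    if mesh.centroids is None:
        compute_triangle_geometry(mesh)
    nt, nv = mesh.n_triangles, len(mesh.vertices)
    rows = np.repeat(np.arange(nt), 3)
    cols = mesh.triangles.ravel()
    data = np.ones(3 * nt, dtype=np.int8)
    incidence = sp.csr_matrix((data, (rows, cols)), shape=(nt, nv))
    shared = (incidence @ incidence.T).tocoo()
    mask = shared.row < shared.col  # strict upper triangle: off-diagonal pairs
    i, j = shared.row[mask], shared.col[mask]
    valid = mesh.valid if mesh.valid is not None else np.ones(nt, bool)
    keep = valid[i] & valid[j]
    i, j = i[keep], j[keep]
    w = np.linalg.norm(mesh.centroids[i] - mesh.centroids[j], axis=1)
    w = np.maximum(w, 1e-9)  # coincident centroids still need a positive edge
    adj = sp.csr_matrix((np.r_[w, w], (np.r_[i, j], np.r_[j, i])),
                        shape=(nt, nt))
    _, labels = connected_components(adj, directed=False)
    return MeshGraph(adj, labels)


def border_triangles(mesh: SurfaceMesh) -> np.ndarray:
    """Indices of triangles owning at least one open (unshared) edge."""
    t = mesh.triangles
    edges = np.concatenate([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]])
    edges = np.sort(edges, axis=1)
    owner = np.tile(np.arange(len(t)), 3)
    order = np.lexsort((edges[:, 1], edges[:, 0]))
    edges, owner = edges[order], owner[order]
    uniq, first, counts = np.unique(edges, axis=0, return_index=True,
                                    return_counts=True)
    open_owner = owner[first[counts == 1]]
    return np.unique(open_owner)


def boundary_distance(mesh: SurfaceMesh, graph: MeshGraph) -> np.ndarray:
    """Geodesic distance from each triangle to the nearest border triangle.

    Border triangles are at distance 0; closed surfaces return inf
    everywhere.
    """
    border = border_triangles(mesh)
    if border.size == 0:
        return np.full(graph.n_nodes, np.inf)
    return graph.geodesic_from(border, min_only=True)
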