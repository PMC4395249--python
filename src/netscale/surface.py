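"""Cortical surface handling and approximate geodesic distances.

The short-range feature of the landmark similarity measure is the length of
the shortest geodesic path between landmark center vertices, constrained to
the cortical sheet.  Exact polyhedral geodesics are out of scope; instead the
surface is approximated by a graph whose nodes are the mesh vertices plus
equally spaced subdivision nodes on every edge, with every pair of nodes that
shares a triangle joined by a straight segment.  Dijkstra on that graph gives
a deterministic approximation that converges from above as the subdivision is
refined: the level-``s`` node set (``2**s - 1`` interior nodes per edge) is a
subset of the level-``s+1`` set and every level-``s`` graph edge persists, so
refining can only shorten paths.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import dijkstra

from .errors import MeshError, UnreachableLandmarkError

__all__ = [
    "TriangleMesh",
    "LandmarkSet",
    "geodesic_matrix",
    "landmark_patches",
    "bipartition_check",
]


@dataclass
class TriangleMesh:
    """Triangle mesh in world millimetres.

    Parameters
    ----------
    vertices : (V, 3) float array
    faces : (F, 3) int array of vertex indices
    """

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        self.validate()

    def validate(self):
        if len(self.faces) and (self.faces.min() < 0 or self.faces.max() >= len(self.vertices)):
            raise MeshError("face references a vertex index out of range")
        a = self.vertices[self.faces[:, 0]]
        b = self.vertices[self.faces[:, 1]]
        c = self.vertices[self.faces[:, 2]]
        area2 = np.linalg.norm(np.cross(b - a, c - a), axis=1)
        if len(area2) and np.any(area2 <= 0.0):
            bad = int(np.flatnonzero(area2 <= 0.0)[0])
            raise MeshError(f"degenerate (zero-area) face at index {bad}")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def edges_unique(self) -> np.ndarray:
        """Sorted unique undirected edges, shape (E, 2)."""
        e = np.vstack([self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]])
        e = np.sort(e, axis=1)
        return np.unique(e, axis=0)

    def to_trimesh(self):
        import trimesh

        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces, process=False)

    @classmethod
    def from_trimesh(cls, tm) -> "TriangleMesh":
        return cls(np.asarray(tm.vertices), np.asarray(tm.faces))


@dataclass
class LandmarkSet:
    """Ordered landmark schema shared across subjects.

    ``ids`` are 1-based consecutive integers; ``center_vertex`` maps each id to
    a vertex index on the subject's mesh.  ``patch_radius`` (mm) defines the
    geodesic patch around each center used for fiber endpoint capture.
    """

    ids: np.ndarray
    center_vertex: np.ndarray
    patch_radius: float = 5.0

    def __post_init__(self):
        self.ids = np.asarray(self.ids, dtype=np.int64).ravel()
        self.center_vertex = np.asarray(self.center_vertex, dtype=np.int64).ravel()
        if len(self.ids) != len(self.center_vertex):
            raise ValueError("ids and center_vertex must have equal length")
        if len(np.unique(self.ids)) != len(self.ids):
            raise ValueError("landmark ids must be unique")
        expected = np.arange(1, len(self.ids) + 1)
        if not np.array_equal(np.sort(self.ids), expected):
            raise ValueError("landmark ids must be the consecutive integers 1..L")

    def __len__(self) -> int:
        return len(self.ids)

    def centers_in_id_order(self) -> np.ndarray:
        """Center vertex indices ordered by landmark id 1..L."""
        order = np.argsort(self.ids)
        return self.center_vertex[order]

    def coordinates(self, mesh: TriangleMesh) -> np.ndarray:
        """(L, 3) center coordinates in id order."""
        return mesh.vertices[self.centers_in_id_order()]


def surface_graph(mesh: TriangleMesh, subdivision: int = 1) -> sparse.csr_matrix:
    """Weighted graph approximating the surface metric.

    Nodes 0..V-1 are the mesh vertices; each edge carries ``2**subdivision - 1``
    equally spaced interior nodes appended after them.  All pairs of nodes
    sharing a face are connected with Euclidean weights.
    """
    if subdivision < 0:
        raise ValueError("subdivision must be >= 0")
    V = mesh.n_vertices
    verts = mesh.vertices
    edges = mesh.edges_unique()
    t = 2**subdivision - 1  # interior nodes per edge

    coords = [verts]
    # edge_nodes[e] -> array of node ids along edge e (including endpoints)
    if t > 0:
        fracs = np.arange(1, t + 1) / (t + 1)
        # interior coords for all edges at once: (E, t, 3)
        p0 = verts[edges[:, 0]][:, None, :]
        p1 = verts[edges[:, 1]][:, None, :]
        interior = p0 + (p1 - p0) * fracs[None, :, None]
        coords.append(interior.reshape(-1, 3))
        edge_interior_ids = V + np.arange(len(edges) * t).reshape(len(edges), t)
    else:
        edge_interior_ids = np.empty((len(edges), 0), dtype=np.int64)
    all_coords = np.vstack(coords)

    # map sorted edge -> row in `edges`
    edge_key = {tuple(e): i for i, e in enumerate(edges.tolist())}

    rows, cols = [], []
    for face in mesh.faces:
        nodes = list(face)
        for u, v in ((face[0], face[1]), (face[1], face[2]), (face[2], face[0])):
            k = (u, v) if u < v else (v, u)
            nodes.extend(edge_interior_ids[edge_key[k]])
        nodes = np.asarray(nodes)
        iu, iv = np.triu_indices(len(nodes), k=1)
        rows.append(nodes[iu])
        cols.append(nodes[iv])
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    lo = np.minimum(rows, cols)
    hi = np.maximum(rows, cols)
    rows, cols = lo, hi
    w = np.linalg.norm(all_coords[rows] - all_coords[cols], axis=1)
    n = len(all_coords)
    # collapse duplicates (edges shared by two faces) keeping one weight
    pairs = rows * n + cols
    order = np.argsort(pairs, kind="stable")
    pairs_sorted = pairs[order]
    w_sorted = w[order]
    uniq, start = np.unique(pairs_sorted, return_index=True)
    wmin = np.minimum.reduceat(w_sorted, start)
    r = (uniq // n).astype(np.int64)
    c = (uniq % n).astype(np.int64)
    g = sparse.coo_matrix(
        (np.concatenate([wmin, wmin]), (np.concatenate([r, c]), np.concatenate([c, r]))),
        shape=(n, n),
    ).tocsr()
    return g


def geodesic_matrix(
    mesh: TriangleMesh,
    landmarks: LandmarkSet,
    subdivision: int = 1,
    cap: float | str | None = "auto",
) -> np.ndarray:
    """Pairwise approximate geodesic distances between landmark centers (mm).

    Distances are measured center vertex to center vertex with Dijkstra on the
    subdivision graph.  Pairs on different mesh components get the finite
    ``cap`` (``"auto"`` = twice the largest finite distance); ``cap=None``
    raises :class:`UnreachableLandmarkError` instead.
    """
    centers = landmarks.centers_in_id_order()
    if centers.max(initial=-1) >= mesh.n_vertices:
        raise MeshError("landmark center vertex outside the mesh")
    g = surface_graph(mesh, subdivision=subdivision)
    dist_all = dijkstra(g, directed=False, indices=centers)
    D = dist_all[:, centers]
    D = 0.5 * (D + D.T)  # symmetric up to float noise already; enforce exactly
    np.fill_diagonal(D, 0.0)
    if np.isinf(D).any():
        if cap is None:
            ii, jj = np.where(np.isinf(D))
            pairs = [(int(i + 1), int(j + 1)) for i, j in zip(ii, jj) if i < j]
            raise UnreachableLandmarkError(pairs)
        finite = D[np.isfinite(D)]
        cap_value = 2.0 * finite.max() if cap == "auto" else float(cap)
        D[np.isinf(D)] = cap_value
    return D


def landmark_patches(
    mesh: TriangleMesh, landmarks: LandmarkSet
) -> dict[int, np.ndarray]:
    """Mesh vertices within ``patch_radius`` geodesically of each center.

    Returns a mapping landmark id -> array of vertex indices (always includes
    the center vertex).  Distances use the plain vertex edge graph, which is
    sufficient for patch membership.
    """
    g = surface_graph(mesh, subdivision=0)
    centers = landmarks.centers_in_id_order()
    dist = dijkstra(g, directed=False, indices=centers, limit=landmarks.patch_radius)
    out = {}
    for row, lid in enumerate(np.sort(landmarks.ids)):
        members = np.flatnonzero(np.isfinite(dist[row]))
        out[int(lid)] = members
    return out


def bipartition_check(distances: np.ndarray, seed: int = 0):
    """Two-way spectral split of landmarks from a geodesic distance matrix.

    Builds the Gaussian affinity of the (max-normalized) distances with the
    median positive off-diagonal as length scale and runs the baseline
    spectral clustering with K=2.  Returns labels in {1, 2}, or ``None`` when
    the distances carry no structure (all off-diagonal entries equal), an
    explicit "no structure" outcome rather than an arbitrary split.
    """
    from .cluster import baseline_split

    D = np.asarray(distances, dtype=float)
    L = D.shape[0]
    if L < 2:
        raise ValueError("bipartition requires at least 2 landmarks")
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")
    off = D[~np.eye(L, dtype=bool)]
    if np.ptp(off) == 0.0:
        return None
    Dn = D / off.max()
    delta = float(np.median(Dn[~np.eye(L, dtype=bool)]))
    delta = max(delta, 1e-12)
    W = np.exp(-(Dn**2) / (2.0 * delta**2))
    labels = baseline_split(W, 2, seed=seed)
    return labels + 1  # {1, 2}
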