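"""Streamline handling and landmark connectivity.

Fibers are 3-D polylines in world millimetres.  The long-range feature of the
similarity measure is built here: fibers are snapped to the cortical surface,
assigned to the pair of landmark patches their endpoints fall in, counted into
a binary connection matrix (a pair is connected when its fiber count strictly
exceeds the threshold), and the hop matrix is the unweighted shortest-path
length on that graph — 1 for a direct connection, m for an m-hop indirect one,
with disconnected pairs set to a finite cap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import shortest_path
from scipy.spatial import cKDTree

from .surface import TriangleMesh, LandmarkSet, landmark_patches

__all__ = [
    "FiberSet",
    "ConnectionMatrix",
    "snap_fiber_endpoints",
    "fiber_landmark_pairs",
    "connection_matrix",
    "hop_matrix",
]


@dataclass
class FiberSet:
    """A collection of streamlines with optional per-point scalars (FA, MD...)."""

    fibers: list  # list of (n_i, 3) float arrays
    scalars: dict = field(default_factory=dict)  # name -> list of (n_i,) arrays

    def __post_init__(self):
        self.fibers = [np.asarray(f, dtype=float).reshape(-1, 3) for f in self.fibers]
        for f in self.fibers:
            if len(f) < 2:
                raise ValueError("every fiber must have at least 2 points")
        for name, arrays in self.scalars.items():
            arrays = [np.asarray(a, dtype=float).ravel() for a in arrays]
            if len(arrays) != len(self.fibers):
                raise ValueError(f"scalar '{name}' must have one array per fiber")
            for a, f in zip(arrays, self.fibers):
                if len(a) != len(f):
                    raise ValueError(f"scalar '{name}' length mismatch with fiber points")
            self.scalars[name] = arrays

    def __len__(self) -> int:
        return len(self.fibers)


@dataclass
class ConnectionMatrix:
    """Binary landmark connectivity with the underlying fiber counts."""

    values: np.ndarray  # L x L binary
    fiber_counts: np.ndarray  # L x L ints
    threshold: int

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.int64)
        self.fiber_counts = np.asarray(self.fiber_counts, dtype=np.int64)


def _ray_mesh_hits(
    vertices: np.ndarray,
    faces: np.ndarray,
    origins: np.ndarray,
    directions: np.ndarray,
    chunk: int = 64,
    max_dist: float | None = None,
):
    """Moller-Trumbore ray-triangle intersection, batched over rays.

    Returns per ray a sorted array of hit parameters t >= 0 (distance along
    the unit direction).  When ``max_dist`` is given, only hits within that
    distance are sought and triangles are prefiltered by a KD-tree on face
    centroids, which is much faster for short rays on large meshes.
    """
    v0 = vertices[faces[:, 0]]
    e1 = vertices[faces[:, 1]] - v0
    e2 = vertices[faces[:, 2]] - v0

    if max_dist is not None:
        centroids = (v0 + vertices[faces[:, 1]] + vertices[faces[:, 2]]) / 3.0
        r_face = np.sqrt(
            np.maximum(
                ((v0 - centroids) ** 2).sum(1),
                np.maximum(
                    ((vertices[faces[:, 1]] - centroids) ** 2).sum(1),
                    ((vertices[faces[:, 2]] - centroids) ** 2).sum(1),
                ),
            )
        ).max()
        tree = cKDTree(centroids)
        out = []
        eps = 1e-12
        for o, d in zip(origins, directions):
            # candidates near the ray's midpoint cover the whole short ray
            mid = o + 0.5 * max_dist * d
            cand = tree.query_ball_point(mid, 0.5 * max_dist + r_face + 1e-9)
            if not cand:
                out.append(np.empty(0))
                continue
            cand = np.asarray(cand)
            h = np.cross(d[None, :], e2[cand])
            a = np.einsum("fk,fk->f", e1[cand], h)
            valid = np.abs(a) > eps
            f = np.where(valid, 1.0 / np.where(valid, a, 1.0), 0.0)
            s = o[None, :] - v0[cand]
            u = f * np.einsum("fk,fk->f", s, h)
            q = np.cross(s, e1[cand])
            v = f * (q @ d)
            t = f * np.einsum("fk,fk->f", e2[cand], q)
            hit = (
                valid
                & (u >= -1e-9)
                & (v >= -1e-9)
                & (u + v <= 1 + 1e-9)
                & (t >= -1e-9)
                & (t <= max_dist + 1e-9)
            )
            out.append(np.sort(t[hit]))
        return out
    out = []
    eps = 1e-12
    for start in range(0, len(origins), chunk):
        O = origins[start:start + chunk]  # (R, 3)
        Dr = directions[start:start + chunk]
        # (R, F, 3) broadcasting
        h = np.cross(Dr[:, None, :], e2[None, :, :])
        a = np.einsum("fk,rfk->rf", e1, h)
        valid = np.abs(a) > eps
        f = np.where(valid, 1.0 / np.where(valid, a, 1.0), 0.0)
        s = O[:, None, :] - v0[None, :, :]
        u = f * np.einsum("rfk,rfk->rf", s, h)
        q = np.cross(s, e1[None, :, :])
        v = f * np.einsum("rk,rfk->rf", Dr, q)
        t = f * np.einsum("fk,rfk->rf", e2, q)
        hit = valid & (u >= -1e-9) & (v >= -1e-9) & (u + v <= 1 + 1e-9) & (t >= -1e-9)
        for r in range(len(O)):
            out.append(np.sort(t[r][hit[r]]))
    return out


def _segment_direction(points: np.ndarray, end: int) -> np.ndarray | None:
    """Unit outward direction of the terminal segment at ``end`` (0=start, 1=end).

    Falls back to earlier segments when the terminal one has zero length.
    """
    if end == 1:
        seq = range(len(points) - 1, 0, -1)
        pick = lambda k: points[k] - points[k - 1]
    else:
        seq = range(0, len(points) - 1)
        pick = lambda k: points[k] - points[k + 1]
    for k in seq:
        d = pick(k)
        n = np.linalg.norm(d)
        if n > 0:
            return d / n
    return None


def snap_fiber_endpoints(
    fibers: FiberSet, mesh: TriangleMesh, max_extension: float = 5.0
):
    """Prolong or shorten fibers so their endpoints reach the cortical surface.

    Each terminal segment is extended along its own direction until the first
    mesh intersection within ``max_extension`` mm; failing that, the terminal
    part of the fiber is truncated back to its last mesh crossing (searched
    within ``max_extension`` of arc length from the end).  Fibers with neither
    are returned unchanged and flagged.

    Returns ``(snapped: FiberSet, flagged: bool array)`` where ``flagged[k]``
    is True when fiber ``k`` has at least one endpoint that could not be
    snapped.
    """
    n = len(fibers)
    pts = [f.copy() for f in fibers.fibers]
    flagged = np.zeros(n, dtype=bool)

    # batch the forward extension rays (2 per fiber)
    origins, directions, which = [], [], []
    for k, f in enumerate(pts):
        for end in (0, 1):
            d = _segment_direction(f, end)
            if d is None:
                flagged[k] = True
                continue
            origins.append(f[-1] if end == 1 else f[0])
            directions.append(d)
            which.append((k, end))
    hits_best = {w: None for w in which}
    if origins:
        origins = np.asarray(origins)
        directions = np.asarray(directions)
        hit_ts = _ray_mesh_hits(
            mesh.vertices, mesh.faces, origins, directions, max_dist=max_extension
        )
        for w, o, d, ts in zip(which, origins, directions, hit_ts):
            if len(ts):
                t0 = float(ts[0])
                hits_best[w] = (t0, o + t0 * d)

    new_fibers = []
    new_scalars = {name: [] for name in fibers.scalars}
    for k in range(n):
        f = pts[k]
        scal = {name: fibers.scalars[name][k].copy() for name in fibers.scalars}
        for end in (1, 0):
            key = (k, end)
            if key not in hits_best:
                continue
            hit = hits_best[key]
            if hit is not None:
                dd, loc = hit
                if dd > 1e-9:
                    if end == 1:
                        f = np.vstack([f, loc])
                        scal = {m: np.append(a, a[-1]) for m, a in scal.items()}
                    else:
                        f = np.vstack([loc, f])
                        scal = {m: np.insert(a, 0, a[0]) for m, a in scal.items()}
                continue
            # truncation fallback: last crossing of the terminal segments
            trunc = _truncate_to_crossing(mesh, f, end, max_extension)
            if trunc is None:
                flagged[k] = True
            else:
                kept = len(trunc)
                if end == 1:
                    scal = {m: np.append(a[: kept - 1], a[kept - 1]) for m, a in scal.items()}
                else:
                    dropped = len(f) - kept
                    scal = {m: np.insert(a[dropped + 1:], 0, a[dropped]) for m, a in scal.items()}
                f = trunc
        new_fibers.append(f)
        for name in new_scalars:
            new_scalars[name].append(scal[name])
    snapped = FiberSet(new_fibers, scalars=new_scalars)
    return snapped, flagged


def _truncate_to_crossing(mesh: TriangleMesh, f: np.ndarray, end: int, max_extension: float):
    """Cut the fiber back to its last mesh crossing near the given end."""
    if end == 0:
        f = f[::-1]
    walked = 0.0
    i = len(f) - 1
    while i > 0 and walked <= max_extension:
        a, b = f[i - 1], f[i]
        seg = b - a
        seg_len = np.linalg.norm(seg)
        if seg_len > 0:
            d = seg / seg_len
            ts = _ray_mesh_hits(
                mesh.vertices, mesh.faces, a[None, :], d[None, :],
                max_dist=seg_len + 1e-9,
            )[0]
            if len(ts):
                # crossing closest to the fiber end
                loc = a + float(ts[-1]) * d
                out = np.vstack([f[:i], loc])
                return out[::-1] if end == 0 else out
        walked += seg_len
        i -= 1
    return None


def fiber_landmark_pairs(
    fibers: FiberSet,
    mesh: TriangleMesh,
    landmarks: LandmarkSet,
) -> list:
    """Assign each fiber to an unordered landmark pair ``(i, j)`` or ``None``.

    A fiber connects landmarks i and j when one endpoint falls inside
    landmark i's surface patch (mesh vertices within ``patch_radius``
    geodesically of the center) and the other inside landmark j's, i != j.
    An endpoint inside several patches goes to the landmark with the nearest
    center.  Endpoint-to-patch membership is resolved through the nearest mesh
    vertex; endpoints farther than ``patch_radius`` from any vertex are not
    captured.
    """
    patches = landmark_patches(mesh, landmarks)
    L = len(landmarks)
    owners: dict[int, list[int]] = {}
    for lid, verts in patches.items():
        for v in verts:
            owners.setdefault(int(v), []).append(lid)
    tree = cKDTree(mesh.vertices)
    centers = landmarks.coordinates(mesh)  # id order

    out = []
    ends = np.array([[f[0], f[-1]] for f in fibers.fibers])  # (n, 2, 3)
    flat = ends.reshape(-1, 3)
    dist, vidx = tree.query(flat)
    dist = dist.reshape(-1, 2)
    vidx = vidx.reshape(-1, 2)
    for k in range(len(fibers)):
        hit = []
        for e in range(2):
            if dist[k, e] > landmarks.patch_radius:
                hit.append(None)
                continue
            cands = owners.get(int(vidx[k, e]), [])
            if not cands:
                hit.append(None)
            elif len(cands) == 1:
                hit.append(cands[0])
            else:
                p = ends[k, e]
                d2 = [np.sum((centers[c - 1] - p) ** 2) for c in cands]
                hit.append(cands[int(np.argmin(d2))])
        i, j = hit
        if i is None or j is None or i == j:
            out.append(None)
        else:
            out.append((min(i, j), max(i, j)))
    return out


def connection_matrix(assignments, L: int, thres: int = 1) -> ConnectionMatrix:
    """Binary connection matrix: 1 iff the fiber count strictly exceeds ``thres``."""
    if thres < 0:
        raise ValueError("thres must be >= 0")
    counts = np.zeros((L, L), dtype=np.int64)
    for a in assignments:
        if a is None:
            continue
        i, j = a
        counts[i - 1, j - 1] += 1
        counts[j - 1, i - 1] += 1
    values = (counts > thres).astype(np.int64)
    np.fill_diagonal(values, 0)
    return ConnectionMatrix(values=values, fiber_counts=counts, threshold=int(thres))


def hop_matrix(C: ConnectionMatrix | np.ndarray, cap: int | None = None) -> np.ndarray:
    """Dijkstra hop counts on the binary connection graph.

    Direct connections give 1 hop; indirect connections the number of edges on
    the shortest path; disconnected pairs the finite ``cap`` (default: the
    number of landmarks L).
    """
    values = C.values if isinstance(C, ConnectionMatrix) else np.asarray(C)
    L = values.shape[0]
    if cap is None:
        cap = L
    hops = shortest_path(values, method="D", directed=False, unweighted=True)
    hops[np.isinf(hops)] = cap
    np.fill_diagonal(hops, 0.0)
    return hops.astype(np.int64) if float(cap).is_integer() else hops
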