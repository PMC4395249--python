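"""Recursive multi-scale network tree and per-scale diagnostics.

Each node of the tree holds a set of landmark ids; splitting a node re-grids
delta on its own sub-matrix, scans the eigengap curves, picks the most stable
(delta*, K*, M*) and calls the baseline spectral split, recursing until the
landmarks cannot be partitioned (or a node is too small / too deep).  The cut
of the tree at depth s gives the scale-s partition, with non-split nodes
persisting downwards, so successive scales are nested by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .cluster import (
    UNSPLITTABLE,
    SpectrumScan,
    baseline_split,
    delta_grid,
    eigengap_curves,
    select_scale,
)
from .errors import LandmarkMismatchError
from .similarity import affinity

__all__ = [
    "TreeNode",
    "NetworkTree",
    "build_tree",
    "consistency_profile",
    "transfer_labels",
    "subnetwork_displacement",
]


@dataclass
class TreeNode:
    node_id: int
    depth: int  # root has depth 1 (= scale 1)
    landmark_ids: np.ndarray  # sorted 1-based ids
    delta_star: float | None = None
    K_star: int | None = None
    M_star: int | None = None
    stability: int | None = None
    children: list = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


class NetworkTree:
    """Recursive partition of landmark ids with per-scale label vectors."""

    def __init__(self, root: TreeNode, n_landmarks: int):
        self.root = root
        self.n_landmarks = n_landmarks
        self.validate()

    # -- structure ---------------------------------------------------------
    def nodes(self):
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    @property
    def n_scales(self) -> int:
        return max(n.depth for n in self.nodes())

    def validate(self):
        """Assert the partition invariants at every node."""
        root_ids = np.sort(self.root.landmark_ids)
        if not np.array_equal(root_ids, np.arange(1, self.n_landmarks + 1)):
            raise ValueError("root must hold the landmark ids 1..L")
        for node in self.nodes():
            if node.children:
                merged = np.sort(np.concatenate([c.landmark_ids for c in node.children]))
                if not np.array_equal(merged, np.sort(node.landmark_ids)):
                    raise ValueError(
                        f"children of node {node.node_id} do not partition it"
                    )

    def scale_labels(self, scale: int) -> np.ndarray:
        """Label per landmark id at a depth cut; non-split nodes persist.

        Returns an int array indexed by landmark id order (position i holds
        the block id of landmark i+1); block ids are node ids of the cut.
        """
        if scale < 1:
            raise ValueError("scale is 1-based")
        labels = np.zeros(self.n_landmarks, dtype=np.int64)

        def assign(node: TreeNode):
            if node.depth == scale or node.is_leaf:
                labels[node.landmark_ids - 1] = node.node_id
                return
            for c in node.children:
                assign(c)

        assign(self.root)
        return labels

    def all_scale_labels(self) -> list[np.ndarray]:
        return [self.scale_labels(s) for s in range(1, self.n_scales + 1)]

    def n_blocks(self, scale: int) -> int:
        return len(np.unique(self.scale_labels(scale)))

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        def enc(node: TreeNode) -> dict:
            return {
                "id": node.node_id,
                "depth": node.depth,
                "landmark_ids": node.landmark_ids.tolist(),
                "delta": node.delta_star,
                "K": node.K_star,
                "M": node.M_star,
                "stability": node.stability,
                "children": [enc(c) for c in node.children],
            }

        return {"n_landmarks": self.n_landmarks, "root": enc(self.root)}

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True)

    @classmethod
    def from_dict(cls, data: dict) -> "NetworkTree":
        def dec(d: dict) -> TreeNode:
            node = TreeNode(
                node_id=int(d["id"]),
                depth=int(d["depth"]),
                landmark_ids=np.asarray(d["landmark_ids"], dtype=np.int64),
                delta_star=d.get("delta"),
                K_star=d.get("K"),
                M_star=d.get("M"),
                stability=d.get("stability"),
            )
            node.children = [dec(c) for c in d.get("children", [])]
            return node

        return cls(dec(data["root"]), int(data["n_landmarks"]))

    @classmethod
    def from_json(cls, text: str) -> "NetworkTree":
        return cls.from_dict(json.loads(text))

    def to_newick(self) -> str:
        """Topology-only Newick string; leaves named by their landmark ids."""

        def enc(node: TreeNode) -> str:
            if node.is_leaf:
                return "-".join(str(i) for i in node.landmark_ids)
            return "(" + ",".join(enc(c) for c in node.children) + f")n{node.node_id}"

        return enc(self.root) + ";"


def build_tree(
    D: np.ndarray,
    min_size: int = 3,
    max_depth: int = 5,
    seed: int = 0,
    kernel_denominator: str = "2dd",
    M_limit: int = 10_000,
) -> NetworkTree:
    """Recursive multi-scale clustering of the combined distance matrix.

    At each node the delta grid is re-derived on the node's own sub-matrix
    and scanned from delta_max down to delta_min; recursion stops when the
    scale selection reports UNSPLITTABLE, the node is smaller than
    ``min_size``, or the node sits at ``max_depth``.
    """
    D = np.asarray(D, dtype=float)
    L = D.shape[0]
    counter = [0]

    def next_id() -> int:
        counter[0] += 1
        return counter[0]

    def grow(ids: np.ndarray, depth: int) -> TreeNode:
        node = TreeNode(node_id=next_id(), depth=depth, landmark_ids=np.sort(ids))
        if len(ids) < min_size or depth >= max_depth:
            return node
        sub = D[np.ix_(ids - 1, ids - 1)]
        import warnings as _warnings

        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")  # constant sub-matrix grid warning
            grid = delta_grid(sub)
        scan = SpectrumScan()
        for delta in grid[::-1]:  # delta_max down to delta_min
            W = affinity(sub, float(delta), kernel_denominator=kernel_denominator)
            scan.append(eigengap_curves(W, delta=float(delta), M_limit=M_limit))
        choice = select_scale(scan)
        if choice is UNSPLITTABLE:
            return node
        K = min(choice.K, len(ids) - 1)
        W = affinity(sub, choice.delta, kernel_denominator=kernel_denominator)
        child_seed = int(
            np.random.SeedSequence([int(seed) & 0x7FFFFFFF, node.node_id]).generate_state(1)[0]
            % 2**31
        )
        labels = baseline_split(W, K, seed=child_seed)
        node.delta_star = choice.delta
        node.K_star = int(K)
        node.M_star = choice.M
        node.stability = choice.stability
        for lab in range(K):
            child_ids = ids[labels == lab]
            node.children.append(grow(child_ids, depth + 1))
        return node

    root = grow(np.arange(1, L + 1), 1)
    return NetworkTree(root, L)


@dataclass
class ConsistencyProfile:
    """Per-scale within-subnetwork consistency (0.5*G + 0.5*P, lower = tighter)."""

    per_scale_mean: np.ndarray  # mean over within-block off-diagonal pairs
    per_block: list  # per scale: {block label: sub-matrix of 0.5G+0.5P}
    singleton_blocks: list  # per scale: block labels excluded (no pairs)


def consistency_profile(tree: NetworkTree, G: np.ndarray, P: np.ndarray) -> ConsistencyProfile:
    """Mean within-subnetwork 0.5*G + 0.5*P at every scale of the tree.

    The combined matrix is a cost: small values mean landmarks are close on
    the cortex and few fiber hops apart, i.e. a *more* consistent
    sub-network.  Pooled over all within-block off-diagonal pairs per scale;
    singleton blocks contribute no pairs and are reported separately.
    """
    C = 0.5 * np.asarray(G, float) + 0.5 * np.asarray(P, float)
    means, per_block, singles = [], [], []
    for s in range(1, tree.n_scales + 1):
        labels = tree.scale_labels(s)
        blocks, skipped = {}, []
        total, count = 0.0, 0
        for b in np.unique(labels):
            idx = np.flatnonzero(labels == b)
            sub = C[np.ix_(idx, idx)]
            blocks[int(b)] = sub
            if len(idx) < 2:
                skipped.append(int(b))
                continue
            off = sub[~np.eye(len(idx), dtype=bool)]
            total += off.sum()
            count += off.size
        means.append(total / count if count else np.nan)
        per_block.append(blocks)
        singles.append(skipped)
    return ConsistencyProfile(np.asarray(means), per_block, singles)


def transfer_labels(tree: NetworkTree, new_landmark_ids) -> dict[int, np.ndarray]:
    """Transfer the model tree's per-scale labels to a new subject by id.

    The landmark schema carries the correspondence, so prediction is pure
    label transfer.  Returns {scale: labels aligned with ``new_landmark_ids``}.
    Raises :class:`LandmarkMismatchError` naming ids absent from the model or
    the subject.
    """
    new_ids = np.asarray(new_landmark_ids, dtype=np.int64).ravel()
    model_ids = set(range(1, tree.n_landmarks + 1))
    missing = model_ids.symmetric_difference(new_ids.tolist())
    if missing:
        raise LandmarkMismatchError(missing)
    out = {}
    for s in range(1, tree.n_scales + 1):
        labels_by_id = tree.scale_labels(s)  # position i -> id i+1
        out[s] = labels_by_id[new_ids - 1]
    return out


def _representative(coords: np.ndarray) -> int:
    """Index of the member with minimum mean distance to the others."""
    n = len(coords)
    if n == 1:
        return 0
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)
    mean_d = d.sum(axis=1) / (n - 1)
    return int(np.argmin(mean_d))


def subnetwork_displacement(
    model_coords: np.ndarray,
    subject_coords: np.ndarray,
    labels: np.ndarray,
):
    """Displacement between model and predicted sub-networks (mm).

    Per block, the representative landmark (minimum mean Euclidean distance to
    the other members, determined independently in each coordinate set) is
    found and the distance between the two representatives reported.
    Returns ``(per_block: {label: mm}, average: mm)``.
    """
    model_coords = np.asarray(model_coords, float)
    subject_coords = np.asarray(subject_coords, float)
    labels = np.asarray(labels)
    if model_coords.shape != subject_coords.shape:
        raise ValueError("coordinate sets must have identical shape")
    per_block = {}
    for b in np.unique(labels):
        idx = np.flatnonzero(labels == b)
        rm = idx[_representative(model_coords[idx])]
        rs = idx[_representative(subject_coords[idx])]
        per_block[int(b)] = float(np.linalg.norm(model_coords[rm] - subject_coords[rs]))
    avg = float(np.mean(list(per_block.values())))
    return per_block, avg
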