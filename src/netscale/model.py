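"""Model/Results interface over the multi-scale clustering pipeline.

``MultiScaleNetworkModel`` holds the group-wise landmark features (the data)
together with the clustering configuration; ``fit`` runs the recursive
multi-scale spectral clustering and returns a ``MultiScaleNetworkResults``
carrying the network tree, the per-scale partitions, consistency diagnostics
and a ``summary()`` table.  Prediction for new subjects (label transfer by
landmark id) and sub-network displacement hang off the results object.
"""

from __future__ import annotations

import numpy as np

from .similarity import GroupFeature, group_features
from .tree import (
    NetworkTree,
    build_tree,
    consistency_profile,
    subnetwork_displacement,
    transfer_labels,
)

__all__ = ["MultiScaleNetworkModel", "MultiScaleNetworkResults"]


class MultiScaleNetworkModel:
    """Multi-scale brain-network model over group-averaged landmark features.

    Parameters
    ----------
    features : GroupFeature
        Combined distance D = alpha*G + (1-alpha)*P with its components.
    min_size : int
        Sub-networks smaller than this are not split further (default 3).
    max_depth : int
        Maximum number of scales (default 5).
    kernel_denominator : {"2dd", "dd"}
        Gaussian kernel reading, exp(-D^2/(2 delta^2)) by default.
    M_limit : int
        Hard cap on the random-walk step scan.
    """

    def __init__(
        self,
        features: GroupFeature,
        min_size: int = 3,
        max_depth: int = 5,
        kernel_denominator: str = "2dd",
        M_limit: int = 10_000,
    ):
        self.features = features
        self.min_size = int(min_size)
        self.max_depth = int(max_depth)
        self.kernel_denominator = kernel_denominator
        self.M_limit = int(M_limit)

    @property
    def n_landmarks(self) -> int:
        return self.features.D.shape[0]

    @classmethod
    def from_subjects(cls, G_list, P_list, alpha: float = 0.5, **kwargs):
        """Build the model from per-subject geodesic and hop matrices."""
        return cls(group_features(G_list, P_list, alpha=alpha), **kwargs)

    @classmethod
    def from_distance(cls, D: np.ndarray, **kwargs):
        """Build the model directly from a combined distance matrix.

        G and P are both set to D so consistency diagnostics remain defined.
        """
        D = np.asarray(D, dtype=float)
        feats = GroupFeature(G=D, P=D, D=D, alpha=0.5, n_subjects=1)
        return cls(feats, **kwargs)

    @classmethod
    def from_scene(cls, scene, alpha: float = 0.5, thres: int = 1,
                   subdivision: int = 1, snap: bool = True, **kwargs):
        """Extract per-subject features from a synthetic scene and build the model."""
        from .pipeline import subject_features

        G_list, P_list = [], []
        for subj in scene.subjects:
            G_n, P_n, _ = subject_features(
                subj.mesh, subj.landmarks, subj.fibers,
                thres=thres, subdivision=subdivision, snap=snap,
            )
            G_list.append(G_n)
            P_list.append(P_n)
        return cls.from_subjects(G_list, P_list, alpha=alpha, **kwargs)

    def fit(self, seed: int = 0) -> "MultiScaleNetworkResults":
        """Run the recursive multi-scale clustering; deterministic per seed."""
        tree = build_tree(
            self.features.D,
            min_size=self.min_size,
            max_depth=self.max_depth,
            seed=seed,
            kernel_denominator=self.kernel_denominator,
            M_limit=self.M_limit,
        )
        return MultiScaleNetworkResults(self, tree, seed)


class MultiScaleNetworkResults:
    """Fitted multi-scale network: tree, per-scale partitions, diagnostics."""

    def __init__(self, model: MultiScaleNetworkModel, tree: NetworkTree, seed: int):
        self.model = model
        self.tree = tree
        self.seed = int(seed)
        self._consistency = None

    # -- partitions --------------------------------------------------------
    @property
    def n_scales(self) -> int:
        return self.tree.n_scales

    def scale_labels(self, scale: int) -> np.ndarray:
        return self.tree.scale_labels(scale)

    def n_subnetworks(self, scale: int) -> int:
        return self.tree.n_blocks(scale)

    @property
    def subnetwork_counts(self) -> list[int]:
        return [self.n_subnetworks(s) for s in range(1, self.n_scales + 1)]

    # -- diagnostics -------------------------------------------------------
    @property
    def consistency(self):
        """Per-scale within-subnetwork mean of 0.5*G + 0.5*P (lower = tighter)."""
        if self._consistency is None:
            self._consistency = consistency_profile(
                self.tree, self.model.features.G, self.model.features.P
            )
        return self._consistency

    # -- prediction --------------------------------------------------------
    def predict(self, new_landmark_ids) -> dict[int, np.ndarray]:
        """Per-scale labels for a new subject sharing the landmark id schema."""
        return transfer_labels(self.tree, new_landmark_ids)

    def displacement(self, model_coords, subject_coords, scale: int):
        """Representative-landmark displacement per sub-network at a scale (mm)."""
        return subnetwork_displacement(
            model_coords, subject_coords, self.scale_labels(scale)
        )

    # -- reporting ---------------------------------------------------------
    def summary(self) -> str:
        lines = []
        lines.append("Multi-scale brain network clustering")
        lines.append("=" * 54)
        f = self.model.features
        lines.append(
            f"Landmarks: {self.model.n_landmarks}    subjects: {f.n_subjects}"
            f"    alpha: {f.alpha:g}    seed: {self.seed}"
        )
        lines.append(
            f"min_size: {self.model.min_size}    max_depth: {self.model.max_depth}"
            f"    kernel: exp(-D^2/{'2' if self.model.kernel_denominator == '2dd' else ''}d^2)"
        )
        lines.append("-" * 54)
        lines.append(f"{'scale':>5} {'sub-networks':>13} {'mean consistency':>18}")
        cons = self.consistency.per_scale_mean
        for s in range(1, self.n_scales + 1):
            lines.append(f"{s:>5} {self.n_subnetworks(s):>13} {cons[s - 1]:>18.4f}")
        lines.append("-" * 54)
        lines.append("splits (node: size -> K at delta*, M*, stability):")
        for node in self.tree.nodes():
            if node.children:
                lines.append(
                    f"  n{node.node_id} (depth {node.depth}): {len(node.landmark_ids)}"
                    f" -> K={node.K_star}  delta*={node.delta_star:.4f}"
                    f"  M*={node.M_star}  stability={node.stability}"
                )
        return "\n".join(lines)

    def to_json(self) -> str:
        return self.tree.to_json()

    def save(self, path):
        with open(path, "w") as fh:
            fh.write(self.to_json())
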