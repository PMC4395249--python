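"""End-to-end pipeline: surfaces + landmarks + fibers -> tree -> bundles.

`subject_features` turns one subject's raw data into the (G_n, P_n) feature
pair; `run_pipeline` ties the stages together for a cohort, writes every
artifact with a JSON manifest recording the full configuration and seed, and
is deterministic given both.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as nio
from .bundles import backbone_bundles, bundle_center, classify_fibers, resample_polyline
from .model import MultiScaleNetworkModel
from .surface import TriangleMesh, LandmarkSet, geodesic_matrix
from .tracts import (
    FiberSet,
    connection_matrix,
    fiber_landmark_pairs,
    hop_matrix,
    snap_fiber_endpoints,
)

__all__ = ["RunConfig", "subject_features", "run_pipeline"]


@dataclass
class RunConfig:
    """Full pipeline configuration, serialized into every run manifest."""

    alpha: float = 0.5
    thres: int = 1
    hop_cap: int | None = None  # None -> number of landmarks
    kernel_denominator: str = "2dd"
    min_size: int = 3
    max_depth: int = 5
    patch_radius: float = 5.0
    classify_threshold: float = 4.0  # mm
    resample_step: float = 1.0  # mm
    subdivision: int = 1
    max_extension: float = 5.0  # mm, endpoint snapping
    seed: int = 0
    surfaces: list = field(default_factory=list)
    landmark_files: list = field(default_factory=list)
    fiber_files: list = field(default_factory=list)
    out_dir: str = "netscale_out"

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.thres < 0:
            raise ValueError("thres must be >= 0")
        if self.classify_threshold <= 0 or self.resample_step <= 0:
            raise ValueError("distances must be positive")
        if self.min_size < 2 or self.max_depth < 1:
            raise ValueError("min_size >= 2 and max_depth >= 1 required")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**{k: v for k, v in d.items() if k in {f.name for f in dataclasses.fields(cls)}})

    def manifest(self) -> dict:
        cfg = self.to_dict()
        digest = hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()
        ).hexdigest()[:16]
        return {"config": cfg, "config_hash": digest, "seed": self.seed}


def subject_features(
    mesh: TriangleMesh,
    landmarks: LandmarkSet,
    fibers: FiberSet,
    thres: int = 1,
    hop_cap: int | None = None,
    subdivision: int = 1,
    snap: bool = True,
    max_extension: float = 5.0,
):
    """One subject's geodesic matrix, hop matrix and fiber assignments."""
    G_n = geodesic_matrix(mesh, landmarks, subdivision=subdivision)
    if snap:
        fibers, _ = snap_fiber_endpoints(fibers, mesh, max_extension=max_extension)
    assignments = fiber_landmark_pairs(fibers, mesh, landmarks)
    C = connection_matrix(assignments, len(landmarks), thres=thres)
    P_n = hop_matrix(C, cap=hop_cap)
    return G_n, P_n, assignments


def run_pipeline(config: RunConfig):
    """Execute geodesic -> connectivity -> similarity -> tree -> bundles.

    Reads the configured per-subject inputs, writes per-stage TSV/JSON
    artifacts plus the run manifest under ``config.out_dir`` and returns the
    fitted results object.  Failures in a later stage leave earlier artifacts
    intact and name the failing stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    n = len(config.surfaces)
    if not (n == len(config.landmark_files) == len(config.fiber_files)):
        raise ValueError("surfaces, landmark_files and fiber_files must align per subject")
    if n == 0:
        raise ValueError("at least one subject is required")

    stage = "inputs"
    try:
        subjects = []
        for s in range(n):
            mesh = nio.read_surface(config.surfaces[s])
            landmarks = nio.read_landmarks(
                config.landmark_files[s], patch_radius=config.patch_radius
            )
            fibers = nio.read_fibers(config.fiber_files[s])
            subjects.append((mesh, landmarks, fibers))

        stage = "features"
        G_list, P_list, assignments_list = [], [], []
        for s, (mesh, landmarks, fibers) in enumerate(subjects):
            G_n, P_n, assignments = subject_features(
                mesh, landmarks, fibers,
                thres=config.thres, hop_cap=config.hop_cap,
                subdivision=config.subdivision, max_extension=config.max_extension,
            )
            ids = np.sort(landmarks.ids)
            nio.write_matrix(out / f"geodesic_subject{s + 1}.tsv", G_n, ids)
            nio.write_matrix(out / f"hops_subject{s + 1}.tsv", P_n, ids)
            G_list.append(G_n)
            P_list.append(P_n)
            assignments_list.append(assignments)

        stage = "similarity"
        model = MultiScaleNetworkModel.from_subjects(
            G_list, P_list, alpha=config.alpha,
            min_size=config.min_size, max_depth=config.max_depth,
            kernel_denominator=config.kernel_denominator,
        )
        ids = np.arange(1, model.n_landmarks + 1)
        nio.write_matrix(out / "combined_distance.tsv", model.features.D, ids)

        stage = "clustering"
        results = model.fit(seed=config.seed)
        (out / "tree.json").write_text(results.to_json())
        labels = {s: results.scale_labels(s).tolist() for s in range(1, results.n_scales + 1)}
        nio.write_labels(out / "scale_labels.tsv", labels)

        stage = "bundles"
        for s, (mesh, landmarks, fibers) in enumerate(subjects):
            atlases = {}
            for scale in range(1, results.n_scales + 1):
                atlas = backbone_bundles(
                    assignments_list[s], results.scale_labels(scale), scale=scale
                )
                if any(atlas.backbone.values()):
                    atlas = classify_fibers(
                        atlas, fibers,
                        threshold=config.classify_threshold,
                        resample_step=config.resample_step,
                    )
                    for lab in sorted(atlas.backbone):
                        members = atlas.members(lab)
                        polys = [resample_polyline(fibers.fibers[m], config.resample_step)
                                 for m in members]
                        atlas.centers[lab] = bundle_center(polys, ids=members)
                atlases[scale] = atlas
            nio.write_atlas(out / f"bundles_subject{s + 1}.tsv", atlases)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(config.manifest(), indent=2, sort_keys=True))
    return results
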