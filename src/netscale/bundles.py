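"""Multi-scale fiber bundles from a landmark partition.

At a given scale, every fiber whose two endpoint landmarks share a
sub-network label joins that sub-network's *backbone* bundle — the most
consistent, correspondence-preserving fibers.  The remaining fibers are then
*classified*: each is assigned to the nearest backbone bundle by the mean
closest point distance, provided it comes within a threshold (default 4 mm);
otherwise it stays unassigned.  Bundle consistency across subjects is
measured by the Hausdorff distance between representative (center) fibers.

Fibers are resampled to a fixed arc-length step before distance computation
so the point-sampled distances are sampling-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.spatial import cKDTree
from scipy.spatial.distance import directed_hausdorff

from .tracts import FiberSet

__all__ = [
    "BundleAtlas",
    "resample_polyline",
    "mean_closest_distance",
    "hausdorff_distance",
    "backbone_bundles",
    "classify_fibers",
    "bundle_center",
    "cross_subject_consistency",
    "bundle_scalar_test",
]

DEFAULT_CLASSIFY_THRESHOLD_MM = 4.0
DEFAULT_RESAMPLE_STEP_MM = 1.0


def resample_polyline(points: np.ndarray, step: float = DEFAULT_RESAMPLE_STEP_MM) -> np.ndarray:
    """Resample a polyline at a fixed arc-length step (endpoints preserved)."""
    points = np.asarray(points, dtype=float)
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total == 0:
        return points[:1].copy()
    n = max(int(np.floor(total / step)), 1)
    targets = np.linspace(0.0, total, n + 1)
    return np.column_stack([np.interp(targets, s, points[:, k]) for k in range(3)])


def mean_closest_distance(fiber_a: np.ndarray, fiber_b: np.ndarray) -> float:
    """Symmetrized mean closest point distance between two polylines (mm)."""
    a = np.asarray(fiber_a, float)
    b = np.asarray(fiber_b, float)
    da = cKDTree(b).query(a)[0].mean()
    db = cKDTree(a).query(b)[0].mean()
    return 0.5 * (da + db)


def hausdorff_distance(fiber_a: np.ndarray, fiber_b: np.ndarray) -> float:
    """Symmetrized Hausdorff distance between two polylines (mm)."""
    a = np.asarray(fiber_a, float)
    b = np.asarray(fiber_b, float)
    return max(directed_hausdorff(a, b)[0], directed_hausdorff(b, a)[0])


@dataclass
class BundleAtlas:
    """Per-scale fiber bundles: backbone members, classified members, centers.

    Fiber ids index into the FiberSet the atlas was built from.
    """

    scale: int
    backbone: dict = field(default_factory=dict)  # label -> list of fiber ids
    classified: dict = field(default_factory=dict)  # label -> list of fiber ids
    centers: dict = field(default_factory=dict)  # label -> fiber id
    unassigned: list = field(default_factory=list)
    threshold: float = DEFAULT_CLASSIFY_THRESHOLD_MM

    def members(self, label) -> list:
        return list(self.backbone.get(label, [])) + list(self.classified.get(label, []))

    def all_backbone_ids(self) -> set:
        return {f for ids in self.backbone.values() for f in ids}


def backbone_bundles(assignments, labels_by_id: np.ndarray, scale: int = 1) -> BundleAtlas:
    """Group fibers whose two endpoint landmarks share a sub-network label.

    ``assignments`` is the per-fiber landmark pair (or None) from
    ``fiber_landmark_pairs``; ``labels_by_id`` maps landmark id i to
    ``labels_by_id[i-1]``.  Cross-block and unassigned fibers are left out.
    """
    atlas = BundleAtlas(scale=scale)
    for fid, pair in enumerate(assignments):
        if pair is None:
            continue
        i, j = pair
        li, lj = labels_by_id[i - 1], labels_by_id[j - 1]
        if li == lj:
            atlas.backbone.setdefault(int(li), []).append(fid)
    for label in atlas.backbone:
        atlas.classified.setdefault(label, [])
    return atlas


def classify_fibers(
    atlas: BundleAtlas,
    fibers: FiberSet,
    remaining=None,
    threshold: float = DEFAULT_CLASSIFY_THRESHOLD_MM,
    resample_step: float = DEFAULT_RESAMPLE_STEP_MM,
    linkage: str = "single",
) -> BundleAtlas:
    """Assign remaining fibers to the nearest backbone bundle within threshold.

    The fiber-to-bundle distance is the minimum mean closest distance over the
    bundle's backbone members (``linkage="single"``) or the distance to its
    center fiber (``linkage="center"``).  A fiber farther than ``threshold``
    from every bundle stays unassigned; exact ties (within 1e-9) go to the
    smaller bundle label.  Re-running on an already-complete atlas is a no-op.
    """
    if not any(atlas.backbone.values()):
        raise ValueError("atlas needs at least one nonempty backbone bundle")
    if linkage not in ("single", "center"):
        raise ValueError("linkage must be 'single' or 'center'")
    taken = atlas.all_backbone_ids() | {
        f for ids in atlas.classified.values() for f in ids
    }
    if remaining is None:
        remaining = [k for k in range(len(fibers)) if k not in taken]
    else:
        remaining = [k for k in remaining if k not in taken]

    res = {k: resample_polyline(fibers.fibers[k], resample_step) for k in range(len(fibers))}
    labels = sorted(atlas.backbone)
    if linkage == "center":
        for lab in labels:
            if lab not in atlas.centers:
                atlas.centers[lab] = bundle_center(
                    [res[f] for f in atlas.backbone[lab]], ids=atlas.backbone[lab]
                )
    for fid in remaining:
        f = res[fid]
        best_label, best_dist = None, np.inf
        for lab in labels:
            if linkage == "single":
                d = min(mean_closest_distance(f, res[m]) for m in atlas.backbone[lab])
            else:
                d = mean_closest_distance(f, res[atlas.centers[lab]])
            if d < best_dist - 1e-9:
                best_label, best_dist = lab, d
            # ties within 1e-9 keep the earlier (smaller) label
        if best_label is not None and best_dist <= threshold:
            atlas.classified.setdefault(best_label, []).append(fid)
        else:
            if fid not in atlas.unassigned:
                atlas.unassigned.append(fid)
    atlas.threshold = threshold
    return atlas


def bundle_center(polylines, ids=None):
    """Representative fiber: the member minimizing the max Hausdorff distance
    to its co-members.  Returns the corresponding entry of ``ids`` (or the
    positional index)."""
    n = len(polylines)
    if n == 0:
        raise ValueError("empty bundle has no center")
    if ids is None:
        ids = list(range(n))
    if n == 1:
        return ids[0]
    H = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            H[i, j] = H[j, i] = hausdorff_distance(polylines[i], polylines[j])
    worst = H.max(axis=1)
    return ids[int(np.argmin(worst))]


def cross_subject_consistency(centers_per_subject: list):
    """Averaged Hausdorff distance of corresponding bundles across subjects.

    ``centers_per_subject`` is a list (one entry per subject) of mappings
    ``{bundle label: center fiber polyline}``.  Only labels present in every
    subject are compared.  Returns ``(per_bundle: {label: mm}, scale_mean)``
    where per-bundle values average over all subject pairs.
    """
    if len(centers_per_subject) < 2:
        raise ValueError("need at least two subjects")
    common = set(centers_per_subject[0])
    for c in centers_per_subject[1:]:
        common &= set(c)
    per_bundle = {}
    for lab in sorted(common):
        ds = []
        for i in range(len(centers_per_subject)):
            for j in range(i + 1, len(centers_per_subject)):
                ds.append(
                    hausdorff_distance(
                        centers_per_subject[i][lab], centers_per_subject[j][lab]
                    )
                )
        per_bundle[lab] = float(np.mean(ds))
    scale_mean = float(np.mean(list(per_bundle.values()))) if per_bundle else np.nan
    return per_bundle, scale_mean


@dataclass
class BundleTestResult:
    statistic: float
    df: float
    pvalue: float
    exact_difference: bool = False  # both groups zero-variance but unequal means


def bundle_scalar_test(group_a, group_b) -> BundleTestResult:
    """Welch two-tailed t-test on per-subject bundle-mean scalar values.

    ``group_a`` / ``group_b`` are 1-D collections of per-subject means of a
    diffusion scalar (FA or MD) along one bundle.  Zero-variance groups with
    unequal means are reported with the ``exact_difference`` flag rather than
    a division-by-zero artifact.
    """
    a = np.asarray(group_a, float).ravel()
    b = np.asarray(group_b, float).ravel()
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 subjects")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if np.isclose(a.mean(), b.mean()):
            return BundleTestResult(0.0, len(a) + len(b) - 2.0, 1.0)
        return BundleTestResult(
            np.inf if a.mean() > b.mean() else -np.inf, len(a) + len(b) - 2.0, 0.0, True
        )
    res = stats.ttest_ind(a, b, equal_var=False)
    sa, sb = va / len(a), vb / len(b)
    df = (sa + sb) ** 2 / (sa**2 / (len(a) - 1) + sb**2 / (len(b) - 1))
    return BundleTestResult(float(res.statistic), float(df), float(res.pvalue))


def per_bundle_scalar_tests(groupA: dict, groupB: dict) -> dict:
    """Run :func:`bundle_scalar_test` for every bundle label common to both groups.

    ``groupA``/``groupB`` map bundle label -> per-subject mean scalar values.
    """
    out = {}
    for lab in sorted(set(groupA) & set(groupB)):
        out[lab] = bundle_scalar_test(groupA[lab], groupB[lab])
    return out
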