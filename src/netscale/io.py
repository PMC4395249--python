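"""Readers and writers for the formats at the pipeline boundary.

Surfaces: PLY / OFF (ASCII, via trimesh) and GIfTI (via nibabel).
Fibers: TRK / TCK (via nibabel.streamlines; TRK voxel coordinates are mapped
to world mm by the header transform on load) and a plain-text fallback —
one fiber per block, one ``x y z [scalars...]`` line per point, blank-line
separated, with an optional ``# scalars: NAME ...`` header.
Matrices and label tables: TSV with a landmark-id header row/column.
Everything round-trips numerically to 1e-9 or better.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .surface import TriangleMesh, LandmarkSet
from .tracts import FiberSet

__all__ = [
    "read_surface", "write_surface",
    "read_landmarks", "write_landmarks",
    "read_fibers", "write_fibers",
    "read_matrix", "write_matrix",
    "write_labels", "read_labels",
    "write_atlas",
    "write_scene",
]


# -- surfaces ---------------------------------------------------------------

def read_surface(path) -> TriangleMesh:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"surface file not found: {path}")
    if path.suffix.lower() == ".gii":
        import nibabel as nib

        img = nib.load(str(path))
        verts = img.get_arrays_from_intent("NIFTI_INTENT_POINTSET")[0].data
        faces = img.get_arrays_from_intent("NIFTI_INTENT_TRIANGLE")[0].data
        return TriangleMesh(verts, faces)
    import trimesh

    tm = trimesh.load(str(path), process=False, force="mesh")
    return TriangleMesh(np.asarray(tm.vertices), np.asarray(tm.faces))


def write_surface(path, mesh: TriangleMesh):
    path = Path(path)
    tm = mesh.to_trimesh()
    if path.suffix.lower() == ".ply":
        data = tm.export(file_type="ply", encoding="ascii")
    elif path.suffix.lower() == ".off":
        data = tm.export(file_type="off")
    else:
        raise ValueError(f"unsupported surface format: {path.suffix}")
    mode = "wb" if isinstance(data, bytes) else "w"
    with open(path, mode) as fh:
        fh.write(data)


# -- landmarks --------------------------------------------------------------

def read_landmarks(path, patch_radius: float = 5.0) -> LandmarkSet:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"landmark file not found: {path}")
    df = pd.read_csv(path, sep="\t")
    for col in ("landmark_id", "vertex_index"):
        if col not in df.columns:
            raise ValueError(f"landmark TSV must have a '{col}' column")
    return LandmarkSet(
        ids=df["landmark_id"].to_numpy(),
        center_vertex=df["vertex_index"].to_numpy(),
        patch_radius=patch_radius,
    )


def write_landmarks(path, landmarks: LandmarkSet):
    pd.DataFrame(
        {"landmark_id": landmarks.ids, "vertex_index": landmarks.center_vertex}
    ).to_csv(path, sep="\t", index=False)


# -- fibers -----------------------------------------------------------------

def read_fibers(path) -> FiberSet:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"fiber file not found: {path}")
    suffix = path.suffix.lower()
    if suffix in (".trk", ".tck"):
        import nibabel as nib

        tractogram = nib.streamlines.load(str(path))  # coordinates in rasmm
        return FiberSet([np.asarray(s) for s in tractogram.streamlines])
    return _read_fibers_text(path)


def _read_fibers_text(path) -> FiberSet:
    fibers, scal_names = [], []
    scalars: dict[str, list] = {}
    block: list[list[float]] = []

    def flush():
        if not block:
            return
        arr = np.asarray(block, dtype=float)
        fibers.append(arr[:, :3])
        for k, name in enumerate(scal_names):
            scalars[name].append(arr[:, 3 + k])
        block.clear()

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if line.startswith("#"):
                if line.lower().startswith("# scalars:"):
                    scal_names = line.split(":", 1)[1].split()
                    scalars = {n: [] for n in scal_names}
                continue
            if not line:
                flush()
                continue
            vals = line.split()
            if len(vals) != 3 + len(scal_names):
                raise ValueError(
                    f"{path}:{lineno}: expected {3 + len(scal_names)} fields, got {len(vals)}"
                )
            try:
                block.append([float(v) for v in vals])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed number ({exc})") from exc
    flush()
    return FiberSet(fibers, scalars=scalars)


def write_fibers(path, fibers: FiberSet):
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".trk", ".tck"):
        import nibabel as nib

        t = nib.streamlines.Tractogram(
            [np.asarray(f) for f in fibers.fibers], affine_to_rasmm=np.eye(4)
        )
        nib.streamlines.save(t, str(path))
        return
    names = sorted(fibers.scalars)
    with open(path, "w") as fh:
        if names:
            fh.write("# scalars: " + " ".join(names) + "\n")
        for k, f in enumerate(fibers.fibers):
            cols = [f] + [fibers.scalars[n][k][:, None] for n in names]
            arr = np.hstack(cols)
            for row in arr:
                fh.write(" ".join(f"{v:.9g}" for v in row) + "\n")
            fh.write("\n")


# -- matrices and labels ----------------------------------------------------

def write_matrix(path, matrix: np.ndarray, landmark_ids):
    ids = [int(i) for i in landmark_ids]
    df = pd.DataFrame(np.asarray(matrix), index=ids, columns=ids)
    df.to_csv(path, sep="\t", index_label="landmark_id")


def read_matrix(path, require_symmetric: bool = True) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    M = df.to_numpy(dtype=float)
    ids = np.asarray([int(c) for c in df.columns])
    if require_symmetric:
        diff = np.abs(M - M.T)
        if diff.size and diff.max() > 1e-9:
            i, j = np.unravel_index(np.argmax(diff), diff.shape)
            raise ValueError(
                f"{path}: matrix not symmetric at cell ({ids[i]}, {ids[j]}): "
                f"{M[i, j]!r} vs {M[j, i]!r}"
            )
    return M, ids


def write_labels(path, labels_per_scale: dict):
    scales = sorted(labels_per_scale)
    n = len(labels_per_scale[scales[0]])
    df = pd.DataFrame({"landmark_id": np.arange(1, n + 1)})
    for s in scales:
        df[f"scale_{s}"] = list(labels_per_scale[s])
    df.to_csv(path, sep="\t", index=False)


def read_labels(path) -> dict:
    df = pd.read_csv(path, sep="\t")
    out = {}
    for col in df.columns:
        if col.startswith("scale_"):
            out[int(col.split("_")[1])] = df[col].to_numpy()
    return out


def write_atlas(path, atlases: dict):
    """Per-scale bundle membership table: fiber id, scale, label, role, center flag."""
    rows = []
    for scale, atlas in sorted(atlases.items()):
        for lab in sorted(atlas.backbone):
            for fid in atlas.backbone[lab]:
                rows.append((fid, scale, lab, "backbone", int(atlas.centers.get(lab) == fid)))
            for fid in atlas.classified.get(lab, []):
                rows.append((fid, scale, lab, "classified", int(atlas.centers.get(lab) == fid)))
        for fid in atlas.unassigned:
            rows.append((fid, scale, -1, "unassigned", 0))
    pd.DataFrame(
        rows, columns=["fiber_id", "scale", "bundle", "role", "is_center"]
    ).to_csv(path, sep="\t", index=False)


# -- synthetic scenes -------------------------------------------------------

def write_scene(out_dir, scene):
    """Write a synthetic scene: PLY meshes, landmark TSVs, TCK fibers, truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for s, subj in enumerate(scene.subjects, start=1):
        write_surface(out / f"subject{s}_surface.ply", subj.mesh)
        write_landmarks(out / f"subject{s}_landmarks.tsv", subj.landmarks)
        write_fibers(out / f"subject{s}_fibers.tck", subj.fibers)
    truth = {
        "hierarchy": list(scene.spec.hierarchy),
        "seed": scene.spec.seed,
        "labels_per_level": {str(k): np.asarray(v).tolist() for k, v in scene.truth_labels.items()},
        "hemisphere": scene.hemisphere.tolist(),
        "planted_pairs": {
            str(s + 1): [list(p) for p in subj.planted_pairs]
            for s, subj in enumerate(scene.subjects)
        },
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=2))
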