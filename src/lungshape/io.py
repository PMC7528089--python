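"""File formats: mesh JSON, point clouds (PLY/OBJ/XYZ), tables, model archives.

Everything is human-inspectable text: meshes and manifests are JSON,
tabular outputs are CSV, point clouds are ascii PLY (preferred), OBJ
vertices or whitespace XYZ.  All writers round-trip through the package's
own readers.
"""

from __future__ import annotations

import json
import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

from .hermite import MeshTopology, QuadElement, MeshValidationError
from .model import ShapeModel

MESH_SCHEMA_VERSION = "1"


class SchemaError(ValueError):
    pass


# ---------------------------------------------------------------------------
# mesh JSON


def mesh_to_dict(mesh: MeshTopology) -> dict:
    return {
        "schema": MESH_SCHEMA_VERSION,
        "nodes": [
            {
                "id": int(nid),
                "x12dof": [float(v) for v in mesh.node_dofs[i].ravel()],
                "landmark": mesh.landmarks[i],
            }
            for i, nid in enumerate(mesh.node_ids)
        ],
        "elements": [
            {"id": int(el.id), "nodes": [int(n) for n in el.node_ids],
             "surface": el.surface}
            for el in mesh.elements
        ],
    }


def mesh_from_dict(d: dict) -> MeshTopology:
    schema = d.get("schema")
    if schema != MESH_SCHEMA_VERSION:
        raise SchemaError(
            f"unsupported mesh schema {schema!r}; this build reads version "
            f"{MESH_SCHEMA_VERSION!r}"
        )
    node_ids = [int(n["id"]) for n in d["nodes"]]
    dofs = np.array([n["x12dof"] for n in d["nodes"]], dtype=float)
    if dofs.ndim != 2 or dofs.shape[1] != 12:
        raise MeshValidationError("each node needs exactly 12 DoF scalars")
    landmarks = [n.get("landmark", "none") for n in d["nodes"]]
    elements = [
        QuadElement(int(e["id"]), tuple(int(n) for n in e["nodes"]), e["surface"])
        for e in d["elements"]
    ]
    return MeshTopology(
        node_ids=node_ids,
        node_dofs=dofs.reshape(-1, 4, 3),
        elements=elements,
        landmarks=landmarks,
    )


def write_mesh(path, mesh: MeshTopology) -> None:
    Path(path).write_text(json.dumps(mesh_to_dict(mesh)))


def read_mesh(path) -> MeshTopology:
    return mesh_from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# point clouds


def write_point_cloud(path, points: np.ndarray) -> None:
    """Format chosen by extension: .ply (ascii), .obj (vertices), .xyz."""
    path = Path(path)
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    ext = path.suffix.lower()
    if ext == ".ply":
        lines = [
            "ply", "format ascii 1.0",
            f"element vertex {len(points)}",
            "property double x", "property double y", "property double z",
            "end_header",
        ]
        lines += [f"{p[0]:.17g} {p[1]:.17g} {p[2]:.17g}" for p in points]
        path.write_text("\n".join(lines) + "\n")
    elif ext == ".obj":
        path.write_text(
            "\n".join(f"v {p[0]:.17g} {p[1]:.17g} {p[2]:.17g}" for p in points)
            + "\n"
        )
    elif ext == ".xyz":
        path.write_text(
            "\n".join(f"{p[0]:.17g} {p[1]:.17g} {p[2]:.17g}" for p in points)
            + "\n"
        )
    else:
        raise ValueError(f"unknown point-cloud extension {ext!r} (ply/obj/xyz)")


def _read_xyz(path: Path) -> np.ndarray:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            parts = stripped.split()
            if len(parts) != 3:
                raise ValueError(
                    f"{path}:{lineno}: expected 3 columns, got {len(parts)}"
                )
            try:
                rows.append([float(v) for v in parts])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
    return np.array(rows, dtype=float).reshape(-1, 3)


def read_point_cloud(path) -> np.ndarray:
    """(n, 3) mm coordinates; format auto-detected from the extension."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise ValueError(f"{path}: empty point-cloud file")
    ext = path.suffix.lower()
    if ext == ".xyz":
        pts = _read_xyz(path)
    elif ext in (".ply", ".obj"):
        loaded = trimesh.load(str(path), process=False)
        pts = np.asarray(loaded.vertices, dtype=float)
    else:
        raise ValueError(f"unknown point-cloud extension {ext!r} (ply/obj/xyz)")
    if pts.size == 0:
        raise ValueError(f"{path}: no points found")
    return pts.reshape(-1, 3)


def read_labels(path) -> pd.DataFrame:
    """Per-point labels CSV with a 'label' column (row order = point order)."""
    df = pd.read_csv(path)
    if "label" not in df.columns:
        raise ValueError(f"{path}: labels CSV needs a 'label' column")
    return df


# ---------------------------------------------------------------------------
# covariates


def read_covariates(path) -> pd.DataFrame:
    """CSV with header subject_id,age,sex,bmi,volume_L."""
    df = pd.read_csv(path)
    from .stats import validate_covariates

    return validate_covariates(df)


def write_covariates(path, df: pd.DataFrame) -> None:
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# model archive


def save_model(out_dir, model: ShapeModel, gpa_mode: str = "unspecified") -> None:
    """Directory archive: manifest.json, mean.csv, modes.csv, singular_values.csv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "manifest.json").write_text(
        json.dumps(
            {
                "schema": MESH_SCHEMA_VERSION,
                "n_subjects": model.n_subjects,
                "n_modes": model.n_modes,
                "gpa_mode": gpa_mode,
                "subject_ids": model.subject_ids,
            }
        )
    )
    np.savetxt(out / "mean.csv", model.mean_vector, delimiter=",")
    np.savetxt(out / "modes.csv", model.modes, delimiter=",")
    np.savetxt(out / "singular_values.csv", model.singular_values, delimiter=",")


def load_model(model_dir) -> tuple[ShapeModel, str]:
    model_dir = Path(model_dir)
    manifest = json.loads((model_dir / "manifest.json").read_text())
    if manifest.get("schema") != MESH_SCHEMA_VERSION:
        raise SchemaError(f"unsupported model schema {manifest.get('schema')!r}")
    mean = np.loadtxt(model_dir / "mean.csv", delimiter=",")
    modes = np.loadtxt(model_dir / "modes.csv", delimiter=",")
    if modes.ndim == 1:
        modes = modes[:, None]
    sv = np.atleast_1d(np.loadtxt(model_dir / "singular_values.csv", delimiter=","))
    model = ShapeModel(
        mean_vector=mean,
        modes=modes,
        singular_values=sv,
        n_subjects=int(manifest["n_subjects"]),
        subject_ids=list(manifest.get("subject_ids", [])),
    )
    return model, manifest.get("gpa_mode", "unspecified")


def file_sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
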