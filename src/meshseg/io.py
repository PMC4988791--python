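"""File I/O: NIfTI volumes, GIFTI and legacy-VTK meshes, model archives,
YAML configuration and tabular subject files.

Masks round-trip as uint8 NIfTI preserving the input affine; meshes
round-trip with vertex order preserved (required for vertex correspondence
across subjects).
"""

from __future__ import annotations

import hashlib
import io as _io
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .errors import MeshSegError
from .mesh import TriangleMesh, VoxelMask
from .model import IntensityModel, ModelHyperparams
from .profiles import ModalityConfig, PriorRule, ProfileSamplingConfig

__all__ = [
    "load_volume", "save_volume", "load_mask", "save_mask",
    "load_mesh", "save_mesh", "save_vertex_data",
    "save_model", "load_model",
    "load_config", "save_config", "config_hash",
    "load_subjects_table",
]

MODEL_SCHEMA_VERSION = 1


# ---------------------------------------------------------------------------
# Volumes
# ---------------------------------------------------------------------------


def load_volume(path) -> tuple:
    """Load a 3D NIfTI volume (optionally gzipped). Returns (data, affine)."""
    path = Path(path)
    if not path.exists():
        raise MeshSegError(f"volume file not found: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise MeshSegError(f"expected a 3D image, got shape {data.shape}: {path}")
    affine = img.affine
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise MeshSegError(f"singular affine in {path}")
    return np.asarray(data), affine


def save_volume(data: np.ndarray, affine: np.ndarray, path) -> None:
    img = nib.Nifti1Image(np.asarray(data), np.asarray(affine, float))
    nib.save(img, str(path))


def load_warp(path):
    """Load a dense displacement field: a 4D NIfTI of shape (X, Y, Z, 3)
    holding mm offsets per voxel. Returns a DenseWarp transform."""
    from .transforms import DenseWarp

    path = Path(path)
    if not path.exists():
        raise MeshSegError(f"warp file not found: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 5 and data.shape[3] == 1:  # FSL-style (X,Y,Z,1,3)
        data = data[:, :, :, 0, :]
    if data.ndim != 4 or data.shape[3] != 3:
        raise MeshSegError(f"warp must have shape (X, Y, Z, 3), got {data.shape}")
    return DenseWarp(data, img.affine)


def load_mask(path) -> VoxelMask:
    data, affine = load_volume(path)
    return VoxelMask(data > 0.5, affine)


def save_mask(mask: VoxelMask, path) -> None:
    img = nib.Nifti1Image(mask.data.astype(np.uint8), mask.affine)
    img.set_data_dtype(np.uint8)
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# Meshes
# ---------------------------------------------------------------------------


def save_mesh(mesh: TriangleMesh, path) -> None:
    """Write a mesh as GIFTI surface (.gii / .surf.gii) or legacy ASCII VTK
    PolyData (.vtk), preserving vertex order."""
    path = Path(path)
    if path.suffix == ".vtk":
        _save_vtk(mesh, path)
        return
    coords = nib.gifti.GiftiDataArray(
        mesh.vertices.astype(np.float32), intent="NIFTI_INTENT_POINTSET")
    tris = nib.gifti.GiftiDataArray(
        mesh.faces.astype(np.int32), intent="NIFTI_INTENT_TRIANGLE")
    nib.save(nib.gifti.GiftiImage(darrays=[coords, tris]), str(path))


def load_mesh(path) -> TriangleMesh:
    path = Path(path)
    if not path.exists():
        raise MeshSegError(f"mesh file not found: {path}")
    if path.suffix == ".vtk":
        return _load_vtk(path)
    img = nib.load(str(path))
    verts = faces = None
    for da in img.darrays:
        if da.intent == nib.nifti1.intent_codes["NIFTI_INTENT_POINTSET"]:
            verts = np.asarray(da.data, float)
        elif da.intent == nib.nifti1.intent_codes["NIFTI_INTENT_TRIANGLE"]:
            faces = np.asarray(da.data, int)
    if verts is None or faces is None:
        raise MeshSegError(f"GIFTI file lacks pointset/triangle arrays: {path}")
    return TriangleMesh(verts, faces).with_normals()


def save_vertex_data(values: np.ndarray, path) -> None:
    """Write a per-vertex scalar map as a GIFTI functional file."""
    da = nib.gifti.GiftiDataArray(np.asarray(values, np.float32),
                                  intent="NIFTI_INTENT_NONE")
    nib.save(nib.gifti.GiftiImage(darrays=[da]), str(path))


def _save_vtk(mesh: TriangleMesh, path: Path) -> None:
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\nmeshseg surface\nASCII\n")
        f.write("DATASET POLYDATA\n")
        f.write(f"POINTS {mesh.n_vertices} float\n")
        for v in mesh.vertices:
            f.write(f"{v[0]:.8g} {v[1]:.8g} {v[2]:.8g}\n")
        nf = len(mesh.faces)
        f.write(f"POLYGONS {nf} {4 * nf}\n")
        for t in mesh.faces:
            f.write(f"3 {t[0]} {t[1]} {t[2]}\n")


def _load_vtk(path: Path) -> TriangleMesh:
    tokens = []
    with open(path) as f:
        lines = f.readlines()
    i = 0
    verts = faces = None
    while i < len(lines):
        line = lines[i].strip()
        up = line.upper()
        if up.startswith("POINTS"):
            n = int(line.split()[1])
            vals = []
            i += 1
            while len(vals) < 3 * n:
                vals.extend(float(x) for x in lines[i].split())
                i += 1
            verts = np.array(vals).reshape(n, 3)
            continue
        if up.startswith("POLYGONS"):
            n = int(line.split()[1])
            vals = []
            i += 1
            while len(vals) < 4 * n:
                vals.extend(int(x) for x in lines[i].split())
                i += 1
            arr = np.array(vals).reshape(n, 4)
            if not np.all(arr[:, 0] == 3):
                raise MeshSegError("VTK polygons must all be triangles")
            faces = arr[:, 1:]
            continue
        i += 1
    if verts is None or faces is None:
        raise MeshSegError(f"could not parse VTK PolyData: {path}")
    return TriangleMesh(verts, faces).with_normals()


# ---------------------------------------------------------------------------
# Model archives (single .npz file with an embedded JSON header)
# ---------------------------------------------------------------------------


def save_model(model: IntensityModel, path) -> None:
    if not model.trained:
        raise MeshSegError("refusing to save an untrained model")
    header = {
        "schema_version": MODEL_SCHEMA_VERSION,
        "config": {"step_mm": model.config.step_mm, "n_steps": model.config.n_steps},
        "hyper": {
            "n0": model.hyper.n0,
            "dirichlet_alpha": model.hyper.dirichlet_alpha,
            "sigma_delta_mm": model.hyper.sigma_delta_mm,
            "smoothness_sd": model.hyper.smoothness_sd,
            "wishart_shape": model.hyper.wishart_shape,
            "max_iter": model.hyper.max_iter,
            "tol": model.hyper.tol,
        },
        "modalities": [
            {"name": m.name, "prior_sd": m.prior_sd, "normalization": m.normalization}
            for m in model.modalities
        ],
        "rules": {
            name: [
                {"modality": r.modality, "template": r.template,
                 "inside": r.inside, "outside": r.outside,
                 "scales_mm": list(r.scales_mm)}
                for r in rules
            ]
            for name, rules in model.rules.items()
        },
        "log_posterior_trace": model.log_posterior_trace,
    }
    arrays = {"header_json": np.frombuffer(json.dumps(header).encode(), dtype=np.uint8)}
    for name in (m.name for m in model.modalities):
        arrays[f"templates__{name}"] = model.prior_templates[name]
        arrays[f"means__{name}"] = model.means[name]
        arrays[f"precisions__{name}"] = model.precisions[name]
        arrays[f"weights__{name}"] = model.weights[name]
    np.savez(str(path), **arrays)


def load_model(path) -> IntensityModel:
    path = Path(path)
    if not path.exists():
        raise MeshSegError(f"model file not found: {path}")
    with np.load(str(path)) as z:
        header = json.loads(bytes(z["header_json"]).decode())
        if header["schema_version"] != MODEL_SCHEMA_VERSION:
            raise MeshSegError("unsupported model schema version")
        config = ProfileSamplingConfig(**header["config"])
        hyper = ModelHyperparams(**header["hyper"])
        modalities = [ModalityConfig(**m) for m in header["modalities"]]
        rules = {
            name: [PriorRule(modality=r["modality"], template=r["template"],
                             inside=r["inside"], outside=r["outside"],
                             scales_mm=tuple(r["scales_mm"]))
                   for r in rl]
            for name, rl in header["rules"].items()
        }
        model = IntensityModel(config=config, modalities=modalities, rules=rules,
                               hyper=hyper, trained=True,
                               log_posterior_trace=header["log_posterior_trace"])
        for m in modalities:
            model.prior_templates[m.name] = z[f"templates__{m.name}"]
            model.means[m.name] = z[f"means__{m.name}"]
            model.precisions[m.name] = z[f"precisions__{m.name}"]
            model.weights[m.name] = z[f"weights__{m.name}"]
    return model


# ---------------------------------------------------------------------------
# Configuration and tables
# ---------------------------------------------------------------------------


def load_config(path) -> dict:
    with open(path) as f:
        cfg = yaml.safe_load(f)
    if not isinstance(cfg, dict):
        raise MeshSegError("configuration must be a YAML mapping")
    return cfg


def save_config(cfg: dict, path) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(cfg, f, sort_keys=True)


def config_hash(cfg: dict) -> str:
    """Stable short hash of a configuration for run reports."""
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def sampling_from_config(cfg: dict) -> ProfileSamplingConfig:
    s = cfg.get("sampling", {})
    if "voxel_mm" in s:
        return ProfileSamplingConfig.from_voxel_size(s["voxel_mm"])
    return ProfileSamplingConfig(step_mm=s.get("step_mm", 0.25),
                                 n_steps=s.get("n_steps", 16))


def modalities_from_config(cfg: dict) -> list:
    return [ModalityConfig(name=m["name"], prior_sd=m["prior_sd"],
                           normalization=m.get("normalization", "relative"))
            for m in cfg["modalities"]]


def rules_from_config(cfg: dict) -> dict:
    out = {}
    for name, rows in cfg["rules"].items():
        out[name] = [
            PriorRule(modality=name, template=r["template"], inside=r["inside"],
                      outside=r["outside"],
                      scales_mm=tuple(r.get("scales_mm", ())))
            for r in rows
        ]
    return out


def load_subjects_table(path) -> pd.DataFrame:
    """TSV with at least columns `id` and `group`; extra columns are
    covariates."""
    df = pd.read_csv(path, sep="\t")
    for col in ("id", "group"):
        if col not in df.columns:
            raise MeshSegError(f"subjects table missing required column {col!r}")
    return df
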