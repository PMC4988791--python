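"""Synthetic multimodal phantoms with known boundaries.

The phantom generator renders small midbrain-like structures — smoothly
deformed ellipsoids — into multimodal 3D volumes whose boundary profiles
follow exactly the edge families the intensity model assumes (sharp step
edges or exponential decay toward the background level), plus independent
Gaussian voxel noise. It also produces cohorts with planted group-level
volume and intensity effects, so segmentation, training and the statistical
pipeline can all be exercised end to end with a known ground truth.

Intensity at a point is

    outside + (inside - outside) * g(d),

where d is the signed radial distance from the point to the truth surface
(negative inside; exact for spheres and a close proxy for the normal
distance on the near-spherical default shapes) and g is 1 for d <= 0 and
either 0 (step) or exp(-d / lambda) (exponential, scale lambda mm) outside.

Default contrasts mimic iron-rich nuclei at high field: a relative
T2*-weighted modality in which the structure is darker than background
(outside/inside ratio 1.33) and an absolute susceptibility modality with
inside values around 0.1-0.15 against a near-zero background.

All randomness flows from the single spec seed; identical specs render
bit-identical volumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from skimage.measure import marching_cubes

from .errors import MeshSegError
from .mesh import TriangleMesh, VoxelMask, mesh_to_mask, signed_distance
from .profiles import ModalityConfig, PriorRule

__all__ = [
    "StructureSpec",
    "ModalityPhantomSpec",
    "PhantomSpec",
    "PhantomTruth",
    "make_structure_truth",
    "render_phantom",
    "generate_cohort",
    "truth_displacements",
    "default_spec",
    "default_rules",
    "default_modality_configs",
]


@dataclass(frozen=True)
class StructureSpec:
    """A deformed-ellipsoid structure: center and semi-axes in mm, plus an
    optional smooth radial deformation amplitude (mm, degree-2 harmonic)."""

    center: tuple
    semi_axes: tuple
    deform_amplitude_mm: float = 0.0

    def __post_init__(self):
        if any(a <= 0 for a in self.semi_axes):
            raise MeshSegError("semi-axes must be positive")


@dataclass(frozen=True)
class ModalityPhantomSpec:
    """Rendering parameters of one modality: plateau levels, edge family and
    voxel noise standard deviation."""

    inside: float
    outside: float
    edge: str = "exponential"  # "step" | "exponential"
    scale_mm: float = 1.0
    noise_sd: float = 0.0

    def __post_init__(self):
        if self.edge not in ("step", "exponential"):
            raise MeshSegError(f"unknown edge family {self.edge!r}")
        if self.edge == "exponential" and self.scale_mm <= 0:
            raise MeshSegError("exponential edge needs positive scale_mm")
        if self.noise_sd < 0:
            raise MeshSegError("noise_sd must be non-negative")


@dataclass(frozen=True)
class PhantomSpec:
    """Full phantom description: grid, structures, modalities and seed."""

    shape: tuple = (48, 48, 48)
    voxel_mm: float = 0.5
    structures: dict = field(default_factory=dict)  # name -> StructureSpec
    modalities: dict = field(default_factory=dict)  # name -> ModalityPhantomSpec
    seed: int = 0

    @property
    def affine(self) -> np.ndarray:
        A = np.eye(4)
        A[:3, :3] *= self.voxel_mm
        A[:3, 3] = self.voxel_mm / 2.0
        return A

    def grid_like(self) -> VoxelMask:
        return VoxelMask(np.zeros(self.shape, bool), self.affine)


@dataclass
class PhantomTruth:
    """Ground truth for one structure: mesh, rasterized mask on the phantom
    grid, and the analytic (undeformed-ellipsoid) volume."""

    mesh: TriangleMesh
    mask: VoxelMask
    analytic_volume_mm3: float


# ---------------------------------------------------------------------------
# Implicit geometry
# ---------------------------------------------------------------------------


def _radial_distance(points: np.ndarray, structure: StructureSpec) -> np.ndarray:
    """Signed radial distance to the (deformed) ellipsoid surface: the
    distance along the ray from the center, negative inside."""
    c = np.asarray(structure.center, float)
    a = np.asarray(structure.semi_axes, float)
    u = points - c
    r = np.linalg.norm(u, axis=-1)
    eps = 1e-12
    n = u / np.maximum(r, eps)[..., None]
    # ellipsoid radius along direction n
    R = 1.0 / np.sqrt(np.maximum(((n / a) ** 2).sum(axis=-1), eps))
    if structure.deform_amplitude_mm != 0.0:
        # fixed smooth degree-2 harmonic bump pattern
        Y = 2.0 * n[..., 0] * n[..., 1] + n[..., 1] * n[..., 2]
        R = R + structure.deform_amplitude_mm * Y
    return r - R


def _grid_points(spec: PhantomSpec) -> np.ndarray:
    ax = [np.arange(s) * spec.voxel_mm + spec.voxel_mm / 2.0 for s in spec.shape]
    ii, jj, kk = np.meshgrid(*ax, indexing="ij")
    return np.stack([ii, jj, kk], axis=-1)


def make_structure_truth(spec: PhantomSpec, structure: str) -> PhantomTruth:
    """Ground-truth mesh, mask and analytic volume for one structure.

    The mesh is extracted by marching cubes at the zero level of the
    continuous radial-distance field (no mask digitization, so vertices sit
    on the analytic surface up to interpolation error); the truth mask is the
    rasterization of that mesh on the phantom grid.
    """
    st = spec.structures[structure]
    c = np.asarray(st.center, float)
    reach = max(st.semi_axes) + abs(st.deform_amplitude_mm)
    fov = np.asarray(spec.shape) * spec.voxel_mm
    if np.any(c - reach < spec.voxel_mm) or np.any(c + reach > fov - spec.voxel_mm):
        raise MeshSegError(
            f"structure {structure!r} is clipped by the field of view")
    pts = _grid_points(spec)
    d = _radial_distance(pts, st)
    verts, faces, _, _ = marching_cubes(d, level=0.0,
                                        spacing=(spec.voxel_mm,) * 3)
    verts = verts + spec.voxel_mm / 2.0  # voxel-center origin
    mesh = TriangleMesh(verts, faces)
    if mesh.enclosed_volume() < 0:
        mesh = TriangleMesh(mesh.vertices, mesh.faces[:, ::-1])
    mesh = mesh.with_normals()
    mask = mesh_to_mask(mesh, spec.grid_like())
    vol = 4.0 / 3.0 * np.pi * float(np.prod(st.semi_axes))
    return PhantomTruth(mesh=mesh, mask=mask, analytic_volume_mm3=vol)


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------


def _edge_decay(d: np.ndarray, mod: ModalityPhantomSpec) -> np.ndarray:
    """g(d): 1 inside, step or exponential decay outside."""
    if mod.edge == "step":
        return (d < 0).astype(float)
    out = np.where(d <= 0, 1.0, np.exp(-np.maximum(d, 0.0) / mod.scale_mm))
    return out


def render_phantom(spec: PhantomSpec) -> tuple:
    """Render all modalities of a phantom.

    Returns (volumes, truths): volumes maps modality name -> (data, affine)
    and truths maps structure name -> PhantomTruth. Rendering is fully
    deterministic given the spec (including its seed).
    """
    pts = _grid_points(spec)
    dists = {name: _radial_distance(pts, st) for name, st in spec.structures.items()}
    truths = {name: make_structure_truth(spec, name) for name in spec.structures}
    rng = np.random.default_rng(spec.seed)
    volumes = {}
    for mname in sorted(spec.modalities):
        mod = spec.modalities[mname]
        vol = np.full(spec.shape, mod.outside, dtype=float)
        for d in dists.values():
            vol += (mod.inside - mod.outside) * _edge_decay(d, mod)
        if mod.noise_sd > 0:
            vol = vol + rng.normal(0.0, mod.noise_sd, size=spec.shape)
        volumes[mname] = (vol, spec.affine)
    return volumes, truths


def truth_displacements(truth: PhantomTruth, reference_mesh: TriangleMesh) -> np.ndarray:
    """True boundary displacement of each reference vertex: the (signed)
    outward travel needed to reach the truth surface. Positive when the truth
    surface lies outside the reference vertex."""
    return -signed_distance(truth.mesh, reference_mesh.vertices)


# ---------------------------------------------------------------------------
# Cohorts with planted effects
# ---------------------------------------------------------------------------


def generate_cohort(spec: PhantomSpec, n_per_group: dict,
                    volume_effect: dict | None = None,
                    intensity_effect: dict | None = None,
                    axis_jitter_sd: float = 0.05,
                    intensity_jitter_sd: float = 0.05,
                    seed: int = 0, render: bool = True) -> tuple:
    """Simulate a cohort around a base phantom spec.

    Parameters
    ----------
    n_per_group : dict group label -> number of subjects (>= 2 each).
    volume_effect : dict group -> fractional volume change of every structure
        (e.g. {"b": -0.10} shrinks group b volumes 10% on average) applied as
        a (1 + effect)^(1/3) scaling of the semi-axes.
    intensity_effect : dict group -> fractional change of each modality's
        inside level.
    axis_jitter_sd / intensity_jitter_sd : per-subject multiplicative
        Gaussian jitter of semi-axes and inside levels.
    render : when False, only subject specs and the manifest are produced
        (no volumes or truth meshes) — cheap mode for power simulations on
        the true parameters.

    Returns (subjects, manifest): subjects is a list of dicts with keys
    ``subject_id``, ``group``, ``spec`` (the subject's own PhantomSpec),
    ``volumes``, ``truths``; the manifest is a DataFrame recording every true
    parameter, from which subjects can be re-rendered bit-identically.
    """
    volume_effect = volume_effect or {}
    intensity_effect = intensity_effect or {}
    for g, n in n_per_group.items():
        if n < 2:
            raise MeshSegError(f"need >= 2 subjects per group, group {g!r} has {n}")
    master = np.random.default_rng(seed)
    subjects = []
    rows = []
    idx = 0
    for group in sorted(n_per_group):
        vscale = (1.0 + volume_effect.get(group, 0.0)) ** (1.0 / 3.0)
        iscale = 1.0 + intensity_effect.get(group, 0.0)
        for _ in range(n_per_group[group]):
            sid = f"sub-{idx:03d}"
            subj_seed = int(master.integers(0, 2 ** 31 - 1))
            jit = np.random.default_rng(subj_seed)
            structures = {}
            for name, st in spec.structures.items():
                axes = tuple(
                    float(a * vscale * (1.0 + jit.normal(0.0, axis_jitter_sd)))
                    for a in st.semi_axes)
                structures[name] = replace(st, semi_axes=axes)
            modalities = {}
            for mname in sorted(spec.modalities):
                mod = spec.modalities[mname]
                inside = float(mod.inside * iscale * (1.0 + jit.normal(0.0, intensity_jitter_sd)))
                modalities[mname] = replace(mod, inside=inside)
            subj_spec = replace(spec, structures=structures,
                                modalities=modalities, seed=subj_seed)
            if render:
                volumes, truths = render_phantom(subj_spec)
            else:
                volumes, truths = None, None
            subjects.append({
                "subject_id": sid, "group": group, "spec": subj_spec,
                "volumes": volumes, "truths": truths,
            })
            row = {"subject_id": sid, "group": group, "seed": subj_seed}
            for name, st in structures.items():
                for ax, val in zip("abc", st.semi_axes):
                    row[f"{name}_semi_{ax}_mm"] = val
                row[f"{name}_true_volume_mm3"] = 4.0 / 3.0 * np.pi * float(np.prod(st.semi_axes))
            for mname, mod in modalities.items():
                row[f"{mname}_inside"] = mod.inside
                row[f"{mname}_outside"] = mod.outside
                row[f"{mname}_noise_sd"] = mod.noise_sd
            rows.append(row)
            idx += 1
    return subjects, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Reference study conditions
# ---------------------------------------------------------------------------


def default_spec(seed: int = 0) -> PhantomSpec:
    """The package's reference phantom: a near-spherical iron-rich nucleus
    (semi-axes 5 x 4.5 x 4 mm) on a 0.5 mm isotropic 48^3 grid, imaged with
    a relative T2*-like modality (structure darker than background,
    outside/inside ratio 1.33, exponential 1 mm edge, noise sd 0.03) and an
    absolute susceptibility-like modality (inside 0.15 vs background 0.05,
    exponential 1 mm edge, noise sd 0.01)."""
    return PhantomSpec(
        shape=(48, 48, 48),
        voxel_mm=0.5,
        structures={
            "nucleus": StructureSpec(center=(12.0, 12.0, 12.0),
                                     semi_axes=(5.0, 4.5, 4.0)),
        },
        modalities={
            "t2s": ModalityPhantomSpec(inside=0.6, outside=0.8,
                                       edge="exponential", scale_mm=1.0,
                                       noise_sd=0.03),
            "qsm": ModalityPhantomSpec(inside=0.15, outside=0.05,
                                       edge="exponential", scale_mm=1.0,
                                       noise_sd=0.01),
        },
        seed=seed,
    )


def default_rules() -> dict:
    """Prior rules matching the default phantom's contrasts: relative
    T2*-like edges (brighter outside) and absolute susceptibility edges."""
    return {
        "t2s": [PriorRule("t2s", "exponential", "self", "self*1.33",
                          scales_mm=(1.0, 3.0))],
        "qsm": [PriorRule("qsm", "exponential", 0.15, 0.05, scales_mm=(1.0, 2.0))],
    }


def default_modality_configs() -> list:
    return [
        ModalityConfig("t2s", prior_sd=0.1, normalization="relative"),
        ModalityConfig("qsm", prior_sd=0.0003, normalization="absolute"),
    ]
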