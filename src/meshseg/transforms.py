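"""Spatial transforms consumed as inputs.

The package does not compute registrations; it consumes per-subject
transforms mapping reference space to subject space, either as a 4x4 affine
(plain-text file, four rows of four numbers) or as a precomputed dense
displacement-field NIfTI (shape (X, Y, Z, 3), mm offsets added to the world
coordinate after interpolation). Identity is the default for phantom work.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .errors import MeshSegError
from .mesh import TriangleMesh

__all__ = ["AffineTransform", "DenseWarp", "apply_to_points", "apply_to_mesh",
           "load_affine_text", "save_affine_text"]


class AffineTransform:
    """World-space affine: y = A[:3,:3] x + A[:3,3]."""

    def __init__(self, matrix: np.ndarray):
        matrix = np.asarray(matrix, float)
        if matrix.shape != (4, 4):
            raise MeshSegError("affine transform must be 4x4")
        self.matrix = matrix

    def __call__(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, float))
        return points @ self.matrix[:3, :3].T + self.matrix[:3, 3]


class DenseWarp:
    """Dense displacement field on a voxel grid: y = x + u(x), with u
    trilinearly interpolated (mm offsets stored per voxel, one volume per
    spatial component)."""

    def __init__(self, field: np.ndarray, affine: np.ndarray):
        field = np.asarray(field, float)
        if field.ndim != 4 or field.shape[3] != 3:
            raise MeshSegError("warp field must be (X, Y, Z, 3)")
        self.field = field
        self.affine = np.asarray(affine, float)

    def __call__(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, float))
        inv = np.linalg.inv(self.affine)
        idx = points @ inv[:3, :3].T + inv[:3, 3]
        disp = np.stack([
            ndimage.map_coordinates(self.field[..., c], idx.T, order=1,
                                    mode="nearest")
            for c in range(3)
        ], axis=1)
        return points + disp


def apply_to_points(transform, points: np.ndarray) -> np.ndarray:
    if transform is None:
        return np.atleast_2d(np.asarray(points, float))
    if callable(transform):
        return transform(points)
    return AffineTransform(transform)(points)


def apply_to_mesh(transform, mesh: TriangleMesh) -> TriangleMesh:
    """Transform mesh vertices; topology preserved, normals recomputed."""
    if transform is None:
        return mesh.with_normals()
    out = TriangleMesh(apply_to_points(transform, mesh.vertices), mesh.faces.copy())
    return out.with_normals()


def load_affine_text(path) -> AffineTransform:
    mat = np.loadtxt(path)
    return AffineTransform(mat)


def save_affine_text(transform: AffineTransform | np.ndarray, path) -> None:
    mat = transform.matrix if isinstance(transform, AffineTransform) else np.asarray(transform)
    np.savetxt(path, mat, fmt="%.10g")
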