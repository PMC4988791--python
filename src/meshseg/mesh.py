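"""Triangle-mesh geometry on top of voxel masks.

This module provides the geometric substrate of the segmentation method:
construction of closed triangle meshes from binary voxel masks, outward
vertex normals, displacement of vertices along their normals, rasterization
of meshes back to voxel masks, and signed distances from points to a mesh.

Conventions (used consistently throughout the package):

* voxel indices are 0-based; world coordinates (mm) are obtained through the
  NIfTI voxel-to-world affine; all mesh geometry lives in world mm;
* meshes are closed, consistently oriented, with outward normals (fixed by
  requiring positive enclosed volume);
* signed distances are negative inside the surface and positive outside;
* vertex displacements are signed offsets along the outward normal, so a
  positive displacement enlarges the structure.

Point-in-mesh queries use an even-odd ray cast along +x with a small
deterministic perturbation of the ray origin, so results are bit-reproducible
and boundary-coincident points are resolved consistently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from skimage.measure import marching_cubes

from .errors import ErosionEmptiedMaskError, MeshSegError, TopologyError

__all__ = [
    "VoxelMask",
    "TriangleMesh",
    "DisplacementField",
    "erode_mask",
    "mask_to_mesh",
    "compute_vertex_normals",
    "apply_displacements",
    "mesh_to_mask",
    "signed_distance",
    "points_inside",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class VoxelMask:
    """A binary occupancy grid with a voxel-to-world affine (mm)."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data).astype(bool)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise MeshSegError(f"mask must be 3D, got shape {self.data.shape}")
        if self.affine.shape != (4, 4):
            raise MeshSegError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise MeshSegError("affine is singular")

    @property
    def shape(self) -> tuple:
        return self.data.shape

    def count(self) -> int:
        return int(self.data.sum())

    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def voxel_centers(self, indices: np.ndarray | None = None) -> np.ndarray:
        """World coordinates (mm) of voxel centers.

        By default returns centers of occupied voxels; pass an (n, 3) index
        array to convert arbitrary indices.
        """
        if indices is None:
            indices = np.argwhere(self.data)
        ijk1 = np.column_stack([indices, np.ones(len(indices))])
        return (self.affine @ ijk1.T).T[:, :3]


@dataclass
class TriangleMesh:
    """A closed, consistently oriented triangle surface in world mm."""

    vertices: np.ndarray
    faces: np.ndarray
    normals: np.ndarray | None = field(default=None)

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshSegError("vertices must be (n, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise MeshSegError("faces must be (m, 3)")
        if self.faces.size and self.faces.max() >= len(self.vertices):
            raise MeshSegError("face index exceeds vertex count")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def face_normals_area(self) -> np.ndarray:
        """Per-face normals scaled by twice the face area (cross products)."""
        v = self.vertices
        f = self.faces
        return np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])

    def face_areas(self) -> np.ndarray:
        return 0.5 * np.linalg.norm(self.face_normals_area(), axis=1)

    def enclosed_volume(self) -> float:
        """Signed enclosed volume by the divergence theorem (positive when
        the mesh is consistently oriented outward)."""
        v = self.vertices[self.faces]
        return float(np.einsum("ij,ij->i", v[:, 0], np.cross(v[:, 1], v[:, 2])).sum() / 6.0)

    def edges(self) -> np.ndarray:
        """Unique undirected edges as an (e, 2) sorted index array."""
        f = self.faces
        e = np.vstack([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
        e = np.sort(e, axis=1)
        return np.unique(e, axis=0)

    def is_closed(self) -> bool:
        """True when every undirected edge is shared by exactly two faces."""
        f = self.faces
        e = np.vstack([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
        e = np.sort(e, axis=1)
        _, counts = np.unique(e, axis=0, return_counts=True)
        return bool(np.all(counts == 2))

    def n_components(self) -> int:
        e = self.edges()
        n = self.n_vertices
        adj = coo_matrix((np.ones(len(e)), (e[:, 0], e[:, 1])), shape=(n, n))
        ncomp, _ = connected_components(adj, directed=False)
        return int(ncomp)

    def euler_characteristic(self) -> int:
        return self.n_vertices - len(self.edges()) + len(self.faces)

    def with_normals(self) -> "TriangleMesh":
        if self.normals is None:
            self.normals = compute_vertex_normals(self)
        return self

    def vertex_areas(self) -> np.ndarray:
        """One-ring barycentric vertex areas (mm^2): one third of each
        incident face's area is assigned to each of its vertices."""
        areas = self.face_areas()
        out = np.zeros(self.n_vertices)
        np.add.at(out, self.faces.ravel(), np.repeat(areas / 3.0, 3))
        return out


@dataclass
class DisplacementField:
    """One signed displacement (mm) per vertex, positive = outward, plus the
    discrete candidate grid inference chose from."""

    values: np.ndarray
    grid: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.grid is not None:
            self.grid = np.asarray(self.grid, dtype=float)

    def __len__(self) -> int:
        return len(self.values)


# ---------------------------------------------------------------------------
# Mask morphology and mesh construction
# ---------------------------------------------------------------------------


def erode_mask(mask: VoxelMask) -> VoxelMask:
    """Morphological erosion with an all-ones 3x3x3 box kernel.

    The grid and affine are unchanged. Raises ErosionEmptiedMaskError when no
    voxel survives (the caller must supply a larger structure).
    """
    if mask.count() == 0:
        raise ErosionEmptiedMaskError("input mask is empty")
    eroded = ndimage.binary_erosion(mask.data, structure=np.ones((3, 3, 3), bool))
    if not eroded.any():
        raise ErosionEmptiedMaskError(
            "erosion-emptied-mask: 3x3x3 box erosion removed all voxels"
        )
    return VoxelMask(eroded, mask.affine)


def _resample_to_isotropic(mask: VoxelMask, target_mm: float) -> VoxelMask:
    """Nearest-neighbour resampling onto an axis-aligned isotropic grid that
    covers the original field of view."""
    shape = np.array(mask.shape, float)
    corners_idx = np.array(
        [[x, y, z] for x in (-0.5, shape[0] - 0.5)
         for y in (-0.5, shape[1] - 0.5)
         for z in (-0.5, shape[2] - 0.5)]
    )
    corners_w = (mask.affine @ np.column_stack([corners_idx, np.ones(8)]).T).T[:, :3]
    lo = corners_w.min(axis=0)
    hi = corners_w.max(axis=0)
    new_shape = np.maximum(np.ceil((hi - lo) / target_mm).astype(int), 1)
    new_affine = np.eye(4)
    new_affine[:3, :3] *= target_mm
    new_affine[:3, 3] = lo + target_mm / 2.0

    ii, jj, kk = np.meshgrid(*[np.arange(s) for s in new_shape], indexing="ij")
    centers = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel(), np.ones(ii.size)])
    world = (new_affine @ centers.T).T
    src_idx = (np.linalg.inv(mask.affine) @ world.T).T[:, :3]
    vals = ndimage.map_coordinates(
        mask.data.astype(np.float32), src_idx.T, order=0, mode="constant", cval=0.0
    )
    return VoxelMask(vals.reshape(new_shape) > 0.5, new_affine)


def _laplacian_smooth(vertices: np.ndarray, faces: np.ndarray,
                      factor: float = 0.2, iterations: int = 10) -> np.ndarray:
    """Umbrella-operator Laplacian smoothing: each vertex moves a fraction of
    the way toward the mean of its edge neighbours, repeatedly."""
    n = len(vertices)
    e = np.vstack([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    e = np.unique(np.sort(e, axis=1), axis=0)
    rows = np.concatenate([e[:, 0], e[:, 1]])
    cols = np.concatenate([e[:, 1], e[:, 0]])
    adj = coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n)).tocsr()
    deg = np.asarray(adj.sum(axis=1)).ravel()
    deg[deg == 0] = 1.0
    v = vertices.copy()
    for _ in range(iterations):
        v = v + factor * (adj @ v / deg[:, None] - v)
    return v


def mask_to_mesh(mask: VoxelMask, target_voxel_mm: float = 1.0,
                 smooth_iterations: int = 10, smooth_factor: float = 0.2) -> TriangleMesh:
    """Build a closed triangle mesh from a binary mask.

    The mask is first eroded with the 3x3x3 box kernel (this suppresses minor
    topological defects), resampled to an isotropic grid of `target_voxel_mm`
    (nearest neighbour), iso-surfaced at the 0.5 level with marching cubes,
    and finally relaxed with a few iterations of mild Laplacian smoothing to
    remove the voxelization staircase. Vertices are in world mm.

    Raises TopologyError when the extracted surface is not a single closed
    component.
    """
    if target_voxel_mm <= 0:
        raise MeshSegError("target_voxel_mm must be positive")
    eroded = erode_mask(mask)
    iso = _resample_to_isotropic(eroded, target_voxel_mm)
    padded = np.pad(iso.data.astype(np.float32), 1, constant_values=0.0)
    verts, faces, _, _ = marching_cubes(padded, level=0.5)
    verts = verts - 1.0  # undo padding offset
    smoothed = _laplacian_smooth(verts, faces, smooth_factor, smooth_iterations)
    # umbrella smoothing shrinks closed surfaces; rescale about the centroid
    # to restore the pre-smoothing enclosed volume (staircase removal only)
    vol0 = abs(TriangleMesh(verts, faces).enclosed_volume())
    vol1 = abs(TriangleMesh(smoothed, faces).enclosed_volume())
    if vol1 > 1e-9:
        centroid = smoothed.mean(axis=0)
        smoothed = centroid + (smoothed - centroid) * (vol0 / vol1) ** (1.0 / 3.0)
    world = (iso.affine @ np.column_stack([smoothed, np.ones(len(smoothed))]).T).T[:, :3]
    mesh = TriangleMesh(world, faces)

    ncomp = mesh.n_components()
    if ncomp != 1:
        raise TopologyError(
            f"topology: surface has {ncomp} connected components (expected 1)",
            n_components=ncomp,
        )
    if not mesh.is_closed():
        raise TopologyError("topology: surface is not closed", n_components=1)
    if mesh.enclosed_volume() < 0:
        mesh = TriangleMesh(mesh.vertices, mesh.faces[:, ::-1])
    areas = mesh.face_areas()
    if np.any(areas <= 1e-12):
        keep = areas > 1e-12
        mesh = TriangleMesh(mesh.vertices, mesh.faces[keep])
        if not mesh.is_closed():
            raise TopologyError("topology: degenerate faces broke closedness")
    return mesh.with_normals()


# ---------------------------------------------------------------------------
# Normals and displacements
# ---------------------------------------------------------------------------


def compute_vertex_normals(mesh: TriangleMesh) -> np.ndarray:
    """Area-weighted average of incident face normals, unit length, oriented
    outward (the orientation giving positive enclosed volume)."""
    faces = mesh.faces
    if mesh.enclosed_volume() < 0:
        faces = faces[:, ::-1]
    v = mesh.vertices
    fn = np.cross(v[faces[:, 1]] - v[faces[:, 0]], v[faces[:, 2]] - v[faces[:, 0]])
    acc = np.zeros_like(v)
    for c in range(3):
        np.add.at(acc, faces[:, c], fn)
    norms = np.linalg.norm(acc, axis=1)
    bad = np.nonzero(norms < 1e-15)[0]
    if bad.size:
        raise MeshSegError(f"zero-length accumulated normal at vertex {bad[0]}")
    return acc / norms[:, None]


def apply_displacements(mesh: TriangleMesh, delta: DisplacementField | np.ndarray) -> TriangleMesh:
    """Move each vertex by its signed displacement along its outward normal.

    Topology is unchanged and normals are recomputed. Self-intersection of
    the displaced surface is NOT checked.
    """
    values = delta.values if isinstance(delta, DisplacementField) else np.asarray(delta, float)
    if len(values) != mesh.n_vertices:
        raise MeshSegError(
            f"displacement length {len(values)} != vertex count {mesh.n_vertices}"
        )
    mesh = mesh.with_normals()
    moved = mesh.vertices + values[:, None] * mesh.normals
    out = TriangleMesh(moved, mesh.faces.copy())
    return out.with_normals()


# ---------------------------------------------------------------------------
# Containment, rasterization and signed distance
# ---------------------------------------------------------------------------

# Deterministic perturbation of ray origins (relative to mesh diagonal):
# avoids rays passing exactly through mesh edges/vertices for grid-aligned
# data, making the even-odd test reproducible bit-for-bit.
_RAY_EPS = (0.61803398875e-6, 0.7548776662e-6)


def points_inside(mesh: TriangleMesh, points: np.ndarray) -> np.ndarray:
    """Even-odd containment test: ray cast along +x from each point.

    Returns a boolean array. Ray origins are perturbed in (y, z) by a fixed,
    deterministic fraction of the mesh bounding-box diagonal so that
    degenerate hits (rays through edges or vertices) are resolved
    reproducibly.
    """
    if not mesh.is_closed():
        raise MeshSegError("containment test requires a closed mesh")
    points = np.atleast_2d(np.asarray(points, float))
    n_pts = len(points)
    diag = float(np.linalg.norm(mesh.vertices.max(0) - mesh.vertices.min(0)))
    py = points[:, 1] + _RAY_EPS[0] * diag
    pz = points[:, 2] + _RAY_EPS[1] * diag
    px = points[:, 0]

    tri = mesh.vertices[mesh.faces]  # (T, 3, 3)
    crossings = np.zeros(n_pts, dtype=np.int64)

    order = np.argsort(py, kind="stable")
    py_s, pz_s, px_s = py[order], pz[order], px[order]

    y0 = tri[:, :, 1].min(axis=1)
    y1 = tri[:, :, 1].max(axis=1)
    z0 = tri[:, :, 2].min(axis=1)
    z1 = tri[:, :, 2].max(axis=1)

    cross_sorted = np.zeros(n_pts, dtype=np.int64)
    for t in range(len(tri)):
        lo = np.searchsorted(py_s, y0[t], side="left")
        hi = np.searchsorted(py_s, y1[t], side="right")
        if hi <= lo:
            continue
        sel = slice(lo, hi)
        zs = pz_s[sel]
        zmask = (zs >= z0[t]) & (zs <= z1[t])
        if not zmask.any():
            continue
        idx = np.nonzero(zmask)[0] + lo
        qy = py_s[idx]
        qz = pz_s[idx]
        a, b, c = tri[t]
        # 2D barycentric test in the (y, z) plane
        d = (b[1] - a[1]) * (c[2] - a[2]) - (c[1] - a[1]) * (b[2] - a[2])
        if d == 0.0:
            continue  # triangle projects to a line; a perturbed ray misses it
        w0 = ((b[1] - qy) * (c[2] - qz) - (c[1] - qy) * (b[2] - qz)) / d
        w1 = ((c[1] - qy) * (a[2] - qz) - (a[1] - qy) * (c[2] - qz)) / d
        w2 = 1.0 - w0 - w1
        hit = np.minimum(np.minimum(w0, w1), w2) >= 0.0
        if not hit.any():
            continue
        hidx = idx[hit]
        xint = w0[hit] * a[0] + w1[hit] * b[0] + w2[hit] * c[0]
        forward = xint > px_s[hidx]
        np.add.at(cross_sorted, hidx[forward], 1)

    crossings[order] = cross_sorted
    return (crossings % 2) == 1


def mesh_to_mask(mesh: TriangleMesh, grid_like: VoxelMask) -> VoxelMask:
    """Rasterize a closed mesh onto a voxel grid.

    A voxel is occupied exactly when its center lies inside the surface
    (even-odd rule with the deterministic ray perturbation). The grid and
    affine are taken from `grid_like`; its occupancy is ignored.
    """
    if not mesh.is_closed():
        raise MeshSegError("mesh_to_mask requires a closed mesh")
    shape = grid_like.shape
    # restrict the test to voxels within the mesh bounding box (+1 voxel pad)
    inv = np.linalg.inv(grid_like.affine)
    vidx = (inv @ np.column_stack([mesh.vertices, np.ones(mesh.n_vertices)]).T).T[:, :3]
    lo = np.maximum(np.floor(vidx.min(0)).astype(int) - 1, 0)
    hi = np.minimum(np.ceil(vidx.max(0)).astype(int) + 1, np.array(shape) - 1)
    out = np.zeros(shape, dtype=bool)
    if np.any(lo > hi):
        return VoxelMask(out, grid_like.affine)
    ranges = [np.arange(lo[d], hi[d] + 1) for d in range(3)]
    ii, jj, kk = np.meshgrid(*ranges, indexing="ij")
    idx = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()])
    centers = (grid_like.affine @ np.column_stack([idx, np.ones(len(idx))]).T).T[:, :3]
    inside = points_inside(mesh, centers)
    out[idx[inside, 0], idx[inside, 1], idx[inside, 2]] = True
    return VoxelMask(out, grid_like.affine)


def _closest_distance_sq(points: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Squared distance from each point to the nearest of the given triangles.

    points: (P, 3); tri: (T, 3, 3). Returns (P,). Vectorized point-triangle
    distance: project onto the triangle plane, and if the projection falls
    outside, take the minimum distance to the three edges.
    """
    a = tri[:, 0]
    ab = tri[:, 1] - a
    ac = tri[:, 2] - a
    n = np.cross(ab, ac)
    nn = np.einsum("ij,ij->i", n, n)
    nn_safe = np.where(nn < 1e-30, 1.0, nn)

    P = len(points)
    best = np.full(P, np.inf)

    chunk = max(1, int(2e6) // max(len(tri), 1))
    for s in range(0, P, chunk):
        p = points[s:s + chunk]  # (p, 3)
        ap = p[:, None, :] - a[None, :, :]  # (p, T, 3)
        # barycentric coordinates of the in-plane projection
        d1 = np.einsum("ptk,tk->pt", ap, ab)
        d2 = np.einsum("ptk,tk->pt", ap, ac)
        dot_abab = np.einsum("ij,ij->i", ab, ab)
        dot_acac = np.einsum("ij,ij->i", ac, ac)
        dot_abac = np.einsum("ij,ij->i", ab, ac)
        denom = dot_abab * dot_acac - dot_abac ** 2
        denom = np.where(np.abs(denom) < 1e-30, 1.0, denom)
        v = (dot_acac * d1 - dot_abac * d2) / denom
        w = (dot_abab * d2 - dot_abac * d1) / denom
        inside = (v >= 0) & (w >= 0) & (v + w <= 1)
        # plane distance where projection is interior
        pn = np.einsum("ptk,tk->pt", ap, n)
        d_plane_sq = pn ** 2 / nn_safe

        # edge distances
        def seg_dist_sq(origin, direction):
            dd = np.einsum("ij,ij->i", direction, direction)
            dd = np.where(dd < 1e-30, 1.0, dd)
            po = p[:, None, :] - origin[None, :, :]
            t = np.clip(np.einsum("ptk,tk->pt", po, direction) / dd, 0.0, 1.0)
            diff = po - t[:, :, None] * direction[None, :, :]
            return np.einsum("ptk,ptk->pt", diff, diff)

        e1 = seg_dist_sq(a, ab)
        e2 = seg_dist_sq(a, ac)
        e3 = seg_dist_sq(tri[:, 1], tri[:, 2] - tri[:, 1])
        d_edge_sq = np.minimum(np.minimum(e1, e2), e3)
        d_sq = np.where(inside, d_plane_sq, d_edge_sq)
        best[s:s + chunk] = d_sq.min(axis=1)
    return best


def signed_distance(mesh: TriangleMesh, points: np.ndarray) -> np.ndarray:
    """Signed Euclidean distance from points to the mesh surface.

    Magnitude is the distance to the nearest point on any triangle; the sign
    is negative inside the closed surface and positive outside.
    """
    if not mesh.is_closed():
        raise MeshSegError("signed_distance requires a closed mesh")
    points = np.atleast_2d(np.asarray(points, float))
    dist = np.sqrt(np.maximum(_closest_distance_sq(points, mesh.vertices[mesh.faces]), 0.0))
    inside = points_inside(mesh, points)
    return np.where(inside, -dist, dist)
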