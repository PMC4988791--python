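"""Mesh geometry: erosion, surface extraction, rasterization, distances."""

import numpy as np
import pytest
import trimesh

import meshseg as ms
from meshseg.errors import ErosionEmptiedMaskError, MeshSegError, TopologyError

from conftest import ball_mask, make_icosphere


class TestErodeMask:
    def test_solid_cube_shrinks_one_voxel_per_face(self):
        data = np.zeros((11, 11, 11), bool)
        data[2:9, 2:9, 2:9] = True  # 7x7x7 cube
        out = ms.erode_mask(ms.VoxelMask(data, np.eye(4)))
        assert out.count() == 125  # 5x5x5
        assert out.data[3:8, 3:8, 3:8].all()

    def test_single_voxel_empties(self):
        data = np.zeros((5, 5, 5), bool)
        data[2, 2, 2] = True
        with pytest.raises(ErosionEmptiedMaskError):
            ms.erode_mask(ms.VoxelMask(data, np.eye(4)))

    def test_anti_extensive_on_random_blob(self):
        rng = np.random.default_rng(3)
        data = rng.random((16, 16, 16)) > 0.4
        data[8, 8, 8] = True
        from scipy import ndimage
        data = ndimage.binary_dilation(data)  # ensure erosion survives
        out = ms.erode_mask(ms.VoxelMask(data, np.eye(4)))
        assert np.all(~out.data | data)  # eroded subset of original


class TestMaskToMesh:
    def test_ball_gives_closed_genus_zero_surface(self):
        mesh = ms.mask_to_mesh(ball_mask(6.0), target_voxel_mm=1.0)
        assert mesh.is_closed()
        assert mesh.n_components() == 1
        assert mesh.euler_characteristic() == 2
        assert np.allclose(np.linalg.norm(mesh.normals, axis=1), 1.0)

    def test_ball_volume_matches_eroded_mask(self):
        # the construction erodes first, so the mesh encloses the eroded mask
        mask = ball_mask(6.0)
        mesh = ms.mask_to_mesh(mask, target_voxel_mm=1.0)
        eroded_vol = ms.mask_volume(ms.erode_mask(mask))
        assert abs(mesh.enclosed_volume() - eroded_vol) / eroded_vol < 0.10

    def test_two_disjoint_blobs_raise_topology_error(self):
        data = np.zeros((40, 20, 20), bool)
        g = np.meshgrid(*[np.arange(s) + 0.5 for s in data.shape], indexing="ij")
        d1 = np.sqrt((g[0] - 10) ** 2 + (g[1] - 10) ** 2 + (g[2] - 10) ** 2)
        d2 = np.sqrt((g[0] - 30) ** 2 + (g[1] - 10) ** 2 + (g[2] - 10) ** 2)
        data = (d1 < 5) | (d2 < 5)
        with pytest.raises(TopologyError) as err:
            ms.mask_to_mesh(ms.VoxelMask(data, np.eye(4)), 1.0)
        assert err.value.n_components == 2

    @pytest.mark.parametrize("radius", [4.0, 6.0, 8.0])
    def test_roundtrip_dice_against_eroded_mask(self, radius):
        mask = ball_mask(radius, shape=(24, 24, 24))
        mesh = ms.mask_to_mesh(mask, target_voxel_mm=1.0)
        back = ms.mesh_to_mask(mesh, mask)
        dice = ms.dice_score(back, ms.erode_mask(mask))
        assert dice >= 0.90


class TestVertexNormals:
    def test_icosphere_normals_are_radial(self, icosphere):
        radial = icosphere.vertices / np.linalg.norm(icosphere.vertices, axis=1,
                                                     keepdims=True)
        cosang = np.einsum("ij,ij->i", icosphere.normals, radial)
        assert np.all(cosang > np.cos(np.deg2rad(5.0)))

    def test_face_interior_vertex_of_cube_gets_axis_normal(self):
        box = trimesh.creation.box(extents=(2, 2, 2))
        box = box.subdivide().subdivide()
        mesh = ms.TriangleMesh(np.array(box.vertices), np.array(box.faces)).with_normals()
        # vertices strictly inside the +x face
        on_face = np.isclose(mesh.vertices[:, 0], 1.0)
        interior = on_face & (np.abs(mesh.vertices[:, 1]) < 0.9) \
            & (np.abs(mesh.vertices[:, 2]) < 0.9)
        assert interior.any()
        assert np.allclose(mesh.normals[interior], [1.0, 0.0, 0.0], atol=1e-8)

    def test_inward_oriented_input_is_flipped_outward(self, icosphere):
        flipped = ms.TriangleMesh(icosphere.vertices.copy(),
                                  icosphere.faces[:, ::-1].copy())
        normals = ms.compute_vertex_normals(flipped)
        radial = flipped.vertices / np.linalg.norm(flipped.vertices, axis=1,
                                                   keepdims=True)
        assert np.all(np.einsum("ij,ij->i", normals, radial) > 0)


class TestApplyDisplacements:
    def test_zero_displacement_is_identity(self, icosphere):
        out = ms.apply_displacements(icosphere, np.zeros(icosphere.n_vertices))
        assert np.array_equal(out.vertices, icosphere.vertices)

    def test_uniform_outward_displacement_expands_sphere(self, icosphere):
        out = ms.apply_displacements(icosphere, np.ones(icosphere.n_vertices))
        radii = np.linalg.norm(out.vertices, axis=1)
        assert abs(radii.mean() - 11.0) / 11.0 < 0.02

    def test_length_mismatch_raises(self, icosphere):
        with pytest.raises(MeshSegError):
            ms.apply_displacements(icosphere, np.zeros(5))


class TestMeshToMask:
    def _grid(self, shape=(6, 6, 6)):
        return ms.VoxelMask(np.zeros(shape, bool), np.eye(4))

    def test_unit_cube_spanning_27_centers(self):
        box = trimesh.creation.box(extents=(3, 3, 3))
        box.apply_translation((2, 2, 2))  # spans [0.5, 3.5]^3
        cube = ms.TriangleMesh(np.array(box.vertices), np.array(box.faces))
        out = ms.mesh_to_mask(cube, self._grid())
        assert out.count() == 27
        assert out.data[1:4, 1:4, 1:4].all()

    def test_small_cube_containing_no_center(self):
        box = trimesh.creation.box(extents=(0.5, 0.5, 0.5))
        box.apply_translation((1.5, 1.5, 1.5))  # spans [1.25, 1.75]^3
        cube = ms.TriangleMesh(np.array(box.vertices), np.array(box.faces))
        assert ms.mesh_to_mask(cube, self._grid()).count() == 0

    def test_convex_polyhedron_matches_halfspace_oracle(self):
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(40, 3)) * 4.0 + 10.0
        hull = trimesh.convex.convex_hull(pts)
        mesh = ms.TriangleMesh(np.array(hull.vertices), np.array(hull.faces))
        grid = ms.VoxelMask(np.zeros((20, 20, 20), bool), np.eye(4))
        out = ms.mesh_to_mask(mesh, grid)
        # oracle: a point is inside a convex polyhedron iff it is on the
        # inner side of every face plane
        centers = grid.voxel_centers(np.argwhere(np.ones((20, 20, 20), bool)))
        normals = np.array(hull.face_normals)
        origins = np.array(hull.triangles_center)
        signed = np.einsum("pfk,fk->pf", centers[:, None, :] - origins[None], normals)
        inside = np.all(signed < 0, axis=1).reshape(20, 20, 20)
        # allow disagreement only on near-boundary voxels
        disagree = out.data != inside
        dist_to_planes = np.abs(signed).min(axis=1).reshape(20, 20, 20)
        assert np.all(dist_to_planes[disagree] < 1e-6)


class TestSignedDistance:
    def test_own_vertices_are_on_the_surface(self, icosphere):
        d = ms.signed_distance(icosphere, icosphere.vertices[::10])
        assert np.all(np.abs(d) < 1e-9)

    def test_sphere_outside_and_inside_queries(self, icosphere):
        d = ms.signed_distance(icosphere, [[0, 0, 13.0], [0, 0, 7.0]])
        assert abs(d[0] - 3.0) < 0.15  # discretized sphere slightly inside r=10
        assert abs(d[1] + 3.0) < 0.15

    def test_lipschitz_along_segments(self, icosphere):
        rng = np.random.default_rng(5)
        a = rng.normal(size=(40, 3)) * 8.0
        b = a + rng.normal(size=(40, 3)) * 2.0
        da = ms.signed_distance(icosphere, a)
        db = ms.signed_distance(icosphere, b)
        seg = np.linalg.norm(a - b, axis=1)
        assert np.all(np.abs(da - db) <= seg + 1e-9)


def test_displacement_grid_and_length_invariants(icosphere):
    f = ms.DisplacementField(np.zeros(icosphere.n_vertices), grid=np.array([-1., 0., 1.]))
    assert len(f) == icosphere.n_vertices
    moved = ms.apply_displacements(icosphere, f)
    assert np.array_equal(moved.vertices, icosphere.vertices)
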