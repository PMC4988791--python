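"""Shared fixtures: analytic meshes and a small phantom segmentation study.

Everything is generated programmatically at test time; the phantom study
(train on 10 synthetic subjects, hold out 5) is session-scoped because
several modules exercise it.
"""

import numpy as np
import pytest
import trimesh

import meshseg as ms


def make_icosphere(radius=10.0, subdivisions=2, center=(0.0, 0.0, 0.0)):
    tm = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    verts = np.array(tm.vertices) + np.asarray(center)
    return ms.TriangleMesh(verts, np.array(tm.faces)).with_normals()


@pytest.fixture(scope="session")
def icosphere():
    return make_icosphere()


@pytest.fixture(scope="session")
def icosahedron():
    tm = trimesh.creation.icosahedron()
    return ms.TriangleMesh(np.array(tm.vertices), np.array(tm.faces)).with_normals()


def ball_mask(radius_vox, shape=(32, 32, 32), voxel_mm=1.0, center=None):
    """Digitized ball: voxel centers within radius (in voxels) of the center."""
    if center is None:
        center = np.array(shape) / 2.0
    aff = np.eye(4)
    aff[:3, :3] *= voxel_mm
    aff[:3, 3] = voxel_mm / 2.0
    grids = np.meshgrid(*[np.arange(s) + 0.5 for s in shape], indexing="ij")
    d = np.sqrt(sum((g - c) ** 2 for g, c in zip(grids, center)))
    return ms.VoxelMask(d < radius_vox, aff)


@pytest.fixture(scope="session")
def phantom_study():
    """Reference end-to-end study: 15 subjects from the default phantom
    conditions, model trained on the first 10, segmentation of the held-out
    5 with the reference MRF weight."""
    spec = ms.default_spec(seed=1)
    subjects, manifest = ms.generate_cohort(spec, {"young": 15}, seed=11)
    train_subj, test_subj = subjects[:10], subjects[10:]
    _, truths = ms.render_phantom(spec)
    ref_mesh = ms.mask_to_mesh(truths["nucleus"].mask, target_voxel_mm=1.0)
    sampling = ms.ProfileSamplingConfig.from_voxel_size(spec.voxel_mm)
    model = ms.train_intensity_model(
        [s["volumes"] for s in train_subj], ref_mesh,
        ms.default_rules(), ms.default_modality_configs(), sampling)
    results = []
    for s in test_subj:
        res = ms.segment_structure(s["volumes"], model, ref_mesh,
                                   ms.MRFConfig(weight=10.0))
        results.append((s, res))
    return {
        "spec": spec,
        "manifest": manifest,
        "ref_mesh": ref_mesh,
        "sampling": sampling,
        "model": model,
        "train_subjects": train_subj,
        "test_results": results,
    }
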