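"""Train the edge-appearance model and segment held-out phantoms.

The full pipeline on synthetic data: build a reference mesh from the mean
phantom's truth mask, train the per-vertex intensity-profile mixture model
on 10 unlabelled subjects, then segment 2 held-out subjects with the
triangle-variance MRF prior (weight 10) and score them against the known
truth masks.
"""

import numpy as np

import meshseg as ms

spec = ms.default_spec(seed=0)
subjects, _ = ms.generate_cohort(spec, {"young": 12}, seed=7)
train_subjects, test_subjects = subjects[:10], subjects[10:]

# reference mesh: eroded mean-phantom mask, iso-surfaced at 1 mm
_, truths = ms.render_phantom(spec)
ref_mesh = ms.mask_to_mesh(truths["nucleus"].mask, target_voxel_mm=1.0)
print(f"reference mesh: {ref_mesh.n_vertices} vertices, "
      f"{len(ref_mesh.faces)} triangles")

sampling = ms.ProfileSamplingConfig.from_voxel_size(spec.voxel_mm)
print(f"profiles: {sampling.k} samples, step {sampling.step_mm} mm, "
      f"span +/- {sampling.positions[-1]} mm")

model = ms.train_intensity_model(
    [s["volumes"] for s in train_subjects], ref_mesh,
    ms.default_rules(), ms.default_modality_configs(), sampling)
print(f"EM converged in {len(model.log_posterior_trace)} iterations")

for subj in test_subjects:
    res = ms.segment_structure(subj["volumes"], model, ref_mesh,
                               ms.MRFConfig(weight=10.0))
    truth = subj["truths"]["nucleus"]
    dice = ms.dice_score(res.mask, truth.mask)
    dtrue = ms.truth_displacements(truth, ref_mesh)
    err = np.mean(np.abs(res.displacements.values - dtrue))
    print(f"{subj['subject_id']}: Dice {dice:.3f}, "
          f"mean |displacement error| {err:.3f} mm, "
          f"{res.report['sweeps']} ICM sweeps")

print("\nDice near 1 means the recovered mask almost coincides with the "
      "truth; the displacement error is the mean gap between the fitted "
      "and true boundary along the mesh normals (the grid step is "
      f"{sampling.step_mm} mm, so errors below ~2 steps are at the "
      "resolution limit).")
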