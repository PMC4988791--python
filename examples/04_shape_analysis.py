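"""Vertex-wise shape analysis with TFCE permutation inference.

Simulates two groups of corresponding meshes — the second group carries a
+1.5 mm local enlargement on one patch — and runs the full inference chain:
translation registration, signed vertex displacements, per-vertex GLM
t-statistics, mesh TFCE and max-statistic FWER-corrected p-values.
"""

import numpy as np
import trimesh

import meshseg as ms

tm = trimesh.creation.icosphere(subdivisions=1, radius=10.0)
reference = ms.TriangleMesh(np.array(tm.vertices), np.array(tm.faces)).with_normals()
V = reference.n_vertices
patch = reference.vertices[:, 2] > 7.0  # the "enlarged" polar cap

rng = np.random.default_rng(1)
n_per_group = 15
data = []
for subject in range(2 * n_per_group):
    delta = rng.normal(0.0, 0.5, V)
    if subject >= n_per_group:  # group "b": planted outward displacement
        delta[patch] += 1.5
    subj_mesh = ms.apply_displacements(reference, delta)
    # random global offset removed by the translation registration
    subj_mesh = ms.TriangleMesh(subj_mesh.vertices + rng.normal(0, 2, 3),
                                subj_mesh.faces)
    data.append(ms.vertex_displacements(subj_mesh, reference))
data = np.array(data)

design = ms.two_group_design(["a"] * n_per_group + ["b"] * n_per_group)
res = ms.permutation_fwer(data, design, reference, n_perm=500, seed=3)

print(f"mean t on the patch:      {res['t'][patch].mean():.2f}")
print(f"mean t off the patch:     {res['t'][~patch].mean():.2f}")
print(f"min corrected p on patch: {res['p_pos'][patch].min():.4f}")
print(f"min corrected p off:      {res['p_pos'][~patch].min():.4f}")
print(f"significant vertices (p <= 0.025, positive tail): "
      f"{(res['p_pos'] <= 0.025).sum()} of {V}")
print("\nThe enlarged patch should reach corrected p <= 0.025 (the per-tail "
      "threshold for a two-sided familywise level of 0.05). TFCE is a "
      "cluster-style statistic, so vertices bordering the patch can share "
      "its suprathreshold component and light up too; vertices far from "
      "the patch should stay null.")
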