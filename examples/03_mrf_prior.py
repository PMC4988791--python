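"""The triangle-variance MRF prior and what the weight w does.

Builds noisy per-vertex displacement likelihoods on an icosphere and runs
ICM at several MRF weights: the prior suppresses vertex-to-vertex
jaggedness while leaving the mean displacement (the overall fit) alone.
"""

import numpy as np
import trimesh

import meshseg as ms

tm = trimesh.creation.icosphere(subdivisions=2, radius=10.0)
mesh = ms.TriangleMesh(np.array(tm.vertices), np.array(tm.faces)).with_normals()

# single-triangle energy: w times the displacement variance of its corners
print("U(1, 1, 1; w=10) =", ms.triangle_energy(1.0, 1.0, 1.0, 10.0))
print("U(0, 0, 3; w=10) =", ms.triangle_energy(0.0, 0.0, 3.0, 10.0))

# likelihoods: true displacement +1 mm everywhere, noisy observations
rng = np.random.default_rng(0)
grid = np.linspace(-2, 2, 17)
noisy_peak = 1.0 + rng.normal(0, 0.5, mesh.n_vertices)
loglik = -((grid[None, :] - noisy_peak[:, None]) ** 2) / (2 * 0.3 ** 2)

print(f"\n{'w':>6} {'mean delta (mm)':>16} {'field sd (mm)':>14} {'sweeps':>7}")
for w in [0.0, 1.0, 10.0, 100.0]:
    out = ms.icm_optimize(loglik, mesh, ms.MRFConfig(weight=w), grid=grid)
    print(f"{w:>6.0f} {out.values.mean():>16.3f} {out.values.std():>14.3f} "
          f"{out.sweeps:>7}")

print("\nThe field standard deviation (surface jaggedness) falls as w "
      "grows, while the mean displacement stays near the true +1 mm: the "
      "prior controls smoothness without dictating the overall shape.")
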