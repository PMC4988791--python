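# meshseg

Mesh-based multimodal segmentation of small, iron-rich deep-brain nuclei
(substantia nigra, subthalamic nucleus, red nucleus) in high-field MRI, with
vertex-wise shape statistics and a synthetic phantom generator so the whole
pipeline is testable without any scanner data.

## Who this is for

Neuroimaging researchers who need reproducible delineations of small
brainstem structures from T2\*-weighted and quantitative susceptibility
mapping (QSM) volumes — structures that show almost no contrast on
T1-weighted images but are clearly visible in iron-sensitive contrasts — and
who then want to compare volumes and local shape across groups.

## The method

A structure is represented by a closed triangle reference mesh. Segmentation
deforms this mesh by moving each vertex *i* a signed distance δ<sub>i</sub>
along its outward normal, choosing the MAP displacements under

- **an intensity likelihood**: at each vertex, short intensity profiles are
  sampled perpendicular to the mesh in every modality and matched against a
  learned per-vertex mixture of edge templates (step edges and exponential
  decays toward the background level, plus a flat "no edge" component).
  Training is unsupervised: rule-based priors specify only the expected
  magnitude, sign and sharpness of each boundary, and an EM algorithm learns
  the actual edge appearance from unlabelled volumes. Modalities are
  combined by conditional independence, so a sharper contrast (typically
  QSM) automatically receives more weight through its learned precision;

- **a Markov random field shape prior** over the displacements,

  p(δ) ∝ exp(−Σ<sub>(i,j,k)∈T</sub> U(δ<sub>i</sub>, δ<sub>j</sub>, δ<sub>k</sub>)),  U = w·[(δ<sub>i</sub>−δ̄)² + (δ<sub>j</sub>−δ̄)² + (δ<sub>k</sub>−δ̄)²],

  summed over all mesh triangles, where δ̄ is the triangle mean. U vanishes
  exactly when the three displacements agree, so the prior penalizes local
  jaggedness; the single weight *w* sets the smoothness and needs no
  training.

Inference is by iterated conditional modes (ICM) on the discrete
displacement grid, initialized at the per-vertex likelihood maxima. The
final mesh is rasterized back to a voxel mask (a voxel belongs to the
structure when its center is inside the surface).

Downstream analysis follows the field's standard chain: Dice overlap and
volumes for evaluation; white-matter-normalized modal intensities for
contrast effects; and vertex-wise shape inference (translation-only
registration, signed distance to the reference surface, per-vertex GLM,
mesh-based threshold-free cluster enhancement and max-statistic permutation
FWER correction, thresholded at p ≤ 0.025 per tail).

## Worked example

```bash
python examples/02_train_and_segment.py
```

trains on 10 synthetic subjects and segments 2 held-out phantoms:

```
reference mesh: 270 vertices, 536 triangles
profiles: 17 samples, step 0.25 mm, span +/- 2.0 mm
EM converged in 14 iterations
sub-010: Dice 0.959, mean |displacement error| 0.115 mm, 3 ICM sweeps
sub-011: Dice 0.977, mean |displacement error| 0.111 mm, 2 ICM sweeps
```

Dice near 1 means the recovered voxel mask nearly coincides with the ground
truth; the displacement error is the mean gap between fitted and true
boundary along the mesh normals — about half a grid step here, i.e. at the
resolution limit of the 0.25 mm displacement grid. The other examples cover
the phantom generator (`01`), the MRF prior's smoothing behavior (`03`),
shape inference with TFCE permutations (`04`) and volume–intensity
regression (`05`).

A thin CLI wraps the same pipeline for shell use
(`meshseg simulate | train | segment | evaluate | shape`); run
`meshseg --help` for the flags.

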