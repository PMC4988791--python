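# Methods

This note documents the models, parameter choices and numerical conventions
implemented in `meshseg`, and what the synthetic phantoms do and do not
establish about behavior on real data.

## Geometry

All geometry lives in world millimetres; voxel indices are 0-based and map
to world coordinates through the NIfTI affine. Meshes are closed, single
component, consistently oriented; orientation is fixed by requiring positive
enclosed volume, and per-vertex normals are area-weighted averages of
incident face normals. Signed distances are negative inside a surface;
displacements are positive outward, so a positive displacement enlarges the
structure.

**Reference-mesh construction.** A voxel mask is eroded with a 3×3×3 box
kernel (suppressing thin connections that would produce topological
defects), resampled to an isotropic target grid by nearest neighbour,
iso-surfaced at the 0.5 level with marching cubes, and relaxed with 10
iterations of umbrella Laplacian smoothing at factor 0.2. Because umbrella
smoothing shrinks closed surfaces, vertices are rescaled about the centroid
after smoothing to restore the pre-smoothing enclosed volume; the smoothing
thus removes the voxelization staircase without biasing the volume. Note
the box erosion shifts the surface inward by about one voxel face-on and up
to √3 voxels diagonally — the reference mesh therefore sits inside the
structure it was traced from, which is intended: segmentation recovers the
boundary by moving vertices outward along their normals. The mesh density
is controlled by the resampling target (1 mm for structures the size of the
substantia nigra or red nucleus; the native 0.5 mm grid for the smaller
subthalamic nucleus).

**Rasterization and containment.** A voxel belongs to a mesh's mask exactly
when its center is inside the surface, decided by an even–odd ray cast along
+x. Ray origins are perturbed in (y, z) by a fixed, irrational fraction
(~10⁻⁶ of the bounding-box diagonal), so rays almost never pass exactly
through mesh edges or vertices and results are bit-reproducible.
Point-to-surface distances combine an exact vectorized point–triangle
distance (plane projection with clamping to the nearest edge segment) with
the same containment test for the sign. Self-intersection of displaced
surfaces is not checked.

## Intensity model

**Sampling geometry.** Profiles have step ℓ = half the voxel size and span
±2 mm: the number of steps is Δ = 2·⌈2 mm/ℓ⌉ (Δ = 16, k = 17 samples at
0.5 mm voxels), with sample positions s_j = (j − Δ/2)·ℓ, negative s inside.
The displacement grid equals the sample grid — the likelihood is only
evaluated where profiles were measured.

**Rule-based priors.** Each modality's expected boundary appearance is
written as rules: a template family (step, or exponential approach to the
outside level with scale λ), and inside/outside levels that are either
absolute (quantitative modalities) or expressed in units of "Self", the
modal intensity inside the structure. Relative modalities are divided by
Self per subject, making them scale-free; templates for them are built with
Self = 1. Each exponential scale contributes one mixture component; one
flat no-edge component (level = mean of the other templates) is always
appended. Templates are blurred with a Gaussian of σ = 0.5 samples,
modelling partial-volume blur at the boundary. The modal intensity uses 100
equal-width bins between the 1st and 99th in-mask percentiles —
deterministic and robust to outliers.

**Generative model and EM.** Per vertex and modality, an observed profile
given component c and displacement δ = n·ℓ is Normal with mean equal to the
component's mean profile translated n grid steps (index-clamped at the
plateau ends) and diagonal per-sample precisions. The displacement is
shared across modalities within a subject and carries a Gaussian prior of
width σ_δ = 2 mm (discretized and normalized on the grid). Conjugate
priors: component means are Normal around the rule template with
pseudo-observation weight n₀ = 3; precisions are Gamma with shape
α⁰ = (k−1)/2 + 3 and rate chosen so the prior mean precision equals
1/(β/f)², with β/f = 0.1 for relative T2\*-like modalities and 0.0003 for
absolute QSM-like modalities; mixture weights are Dirichlet with α = 2 for
all components. Training is MAP-EM: the E-step computes joint
responsibilities over (component, displacement); the M-step performs the
exact conjugate MAP updates, so the log-posterior is non-decreasing (an
asserted invariant). Initialization is deterministic at the prior; EM runs
at most 100 iterations to a relative tolerance of 10⁻⁶. Means are trained
fully per-vertex with shared hyperparameters; sharing components across
vertices would be the main alternative and would trade spatial specificity
for statistical strength.

Precisions are diagonal (one variance per sample position): with k ≈ 17 and
tens of training subjects, full covariances are not identifiable.

**Displacement posterior.** At test time the per-vertex log-posterior over
the grid adds, across modalities, the log of the weighted component mixture
evaluated at each candidate shift, plus the displacement log-prior, then
normalizes. Two boundary conventions follow from the clamped shifting and
are worth knowing: a profile flat at the *inside* level is inferred as
"boundary beyond the sampled window" (argmax at the largest positive grid
displacement) — the plateau-extended templates fit it exactly there — while
a profile at the flat component's level carries no boundary information and
the symmetric prior puts the argmax at zero.

**Identifiability.** The template's edge position and the displacement
distribution are only weakly identified against each other (anchored by n₀
and the δ-prior). Consequently the learned boundary convention can differ
from any external "truth" definition by a small constant offset when the
prior rules mis-state the contrast levels — the practical reason the rule
tables should reflect the data's actual plateau levels, and a caveat shared
with any self-trained edge model.

## Shape prior and inference

The MRF couples the three vertices of each triangle with energy
U = w·Σ(δ−δ̄)², the (unnormalized) sum of squared deviations from the
triangle mean: zero iff the displacements agree, invariant to adding a
constant to the whole field. The weight w is the only shape parameter:
10 for the substantia-nigra/red-nucleus setup, 100 for the denser
subthalamic-nucleus mesh (a denser mesh has more triangles per unit area,
so matching smoothness needs a larger per-triangle weight).

ICM visits vertices in ascending index order, setting each to the grid
value minimizing its negative log-likelihood plus the energies of its
incident triangles, starting from the likelihood-only maxima. Ties break
toward smaller |δ|, then toward negative δ (deterministic, mildly
shrinking). Iteration stops after a sweep with no changes, or 100 sweeps.
Every accepted update lowers the posterior energy, so termination on the
finite grid is guaranteed. ICM finds local optima; because the profile
likelihoods are smooth and the initialization is near-optimal, it matches
the global optimum in ≈96% of model-regime random instances (verified
against exhaustive enumeration on a 12-vertex mesh), and larger w smooths
the output field in aggregate, though individual instances can land in
different local optima at different weights.

## Shape statistics

All subjects share the reference mesh's vertex indexing and vertices move
only along normals, so same-index vertices correspond across subjects.
Subject meshes are registered to the reference by translation only (the
closed form: centroid difference) — rotations are ill-determined for
near-spherical structures and scaling is removed upstream by the supplied
affines — and each vertex's signed distance to the reference surface is the
dependent variable. Per-vertex OLS with a contrast gives t-statistics
(vectorized; with a two-group design this is the pooled-variance two-sample
t). TFCE integrates e(h)^E · h^H · dh over thresholds (defaults H = 2,
E = 1, dh = max/100 — standard surface-TFCE practice), where e(h) is the
one-ring barycentric vertex area of the suprathreshold connected component
containing the vertex; the negative tail is enhanced from the negated map.
Permutation inference freely permutes group labels (the max-TFCE statistic
over vertices per permutation forms the null), giving corrected
p = (1 + #{max ≥ observed})/(n_perm + 1); when all two-group assignments
can be enumerated within the permutation budget the enumeration is used and
the result is seed-free. Both contrast signs are tested; thresholding each
tail at 0.025 gives a two-sided familywise level of 0.05. The default
design is group-only; covariate columns are accepted.

## Evaluation metrics

Dice = 2|A∩B|/(|A|+|B|) on identical grids; volume = voxel count × |det| of
the affine's 3×3 block. Structure intensities are modal intensities inside
the eroded intersection of two raters' masks (intersection first, then one
3×3×3 box erosion — the conservative order), divided by the mean
white-matter intensity for relative modalities and used raw for
quantitative ones. Volume–intensity associations use per-group and pooled
OLS with two-sided slope p-values, flagged at 0.05.

## Synthetic phantoms

Phantoms render smoothly deformed ellipsoids into multimodal volumes:
intensity = outside + (inside − outside)·g(d) with g the step or
exponential edge family, plus iid Gaussian voxel noise. The boundary
coordinate d is the signed *radial* distance (along the ray from the
structure center) — exact for spheres and within a cosine factor of the
normal distance for the near-spherical default shapes; strongly eccentric
structures would need a true distance transform. Truth meshes come from
marching cubes on the continuous distance field (so vertices sit on the
analytic surface), and the truth mask is that mesh's rasterization, keeping
mask and mesh exactly consistent.

Default conditions (one choice, used everywhere): a 48³ grid at 0.5 mm; a
nucleus with semi-axes 5 × 4.5 × 4 mm (volume ≈ 377 mm³, the scale of a
midbrain nucleus); a relative T2\*-like modality with the structure darker
than background (inside 0.6, outside 0.8 — ratio 1.33, matching the
rule-table magnitude), exponential 1 mm edge, noise sd 0.03 (≈ 7:1
edge-contrast-to-noise); and an absolute susceptibility-like modality
(inside 0.15, outside 0.05 — the rule-table values), exponential 1 mm edge,
noise sd 0.01. Cohorts jitter semi-axes and inside levels by 5%
multiplicative Gaussian noise per subject and can plant fractional group
volume/intensity effects; every parameter is recorded in a manifest and all
randomness flows from one seed (subject seeds are spawned from it), making
re-rendering bit-identical.

What the phantoms do not emulate: bias fields, anatomy-dependent intensity
structure, partial-volume mixtures of more than two tissues, inter-modality
misregistration, and non-ellipsoidal shapes. Passing the phantom studies
therefore demonstrates the correctness of the estimation machinery under
the model's own assumptions — not robustness to the full messiness of 7 T
data, for which the rule tables and the unsupervised training are the
designed adaptation mechanism.

## Problem sizes

The reference end-to-end study trains on 10 subjects and segments 5
held-out phantoms on the 48³ grid with a ~270-vertex reference mesh; the
ICM-versus-exhaustive check enumerates all 3¹² configurations on a
12-vertex icosahedron (50 instances); permutation calibration uses 100 null
cohorts of 15 + 15 subjects with 250 permutations on a 42-vertex sphere,
and power uses 10 replicates at 500 permutations. These sizes make the
whole suite run in minutes on one CPU while keeping every estimate's
Monte-Carlo error well inside the asserted tolerances.

## Known limitations

- Vertex correspondence is nominal (same index), not geodesic; large
  displacements shear the correspondence slightly.
- ICM is a local optimizer; pathological likelihood tables (far outside the
  model's smooth regime) can leave it several percent above the global
  optimum.
- The displacement grid caps recoverable offsets at ±2 mm; structures
  misaligned by more need better initial transforms.
- No bias-field correction or cross-scanner harmonization; relative
  modalities rely on the Self normalization only.
- Transforms are consumed, never estimated; registration quality bounds
  segmentation quality.
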