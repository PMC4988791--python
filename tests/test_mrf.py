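"""Triangle-variance MRF prior and ICM MAP inference."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import meshseg as ms
from meshseg.errors import MeshSegError


class TestTriangleEnergy:
    @given(c=st.floats(-50, 50), w=st.floats(0, 1e3))
    @settings(max_examples=50, deadline=None)
    def test_agreeing_displacements_cost_nothing(self, c, w):
        assert ms.triangle_energy(c, c, c, w) == pytest.approx(0.0, abs=1e-12)

    def test_direct_evaluation(self):
        # mean 1, squared deviations 1 + 1 + 4 = 6, times w = 10
        assert ms.triangle_energy(0.0, 0.0, 3.0, 10.0) == pytest.approx(60.0)

    @given(di=st.floats(-5, 5), dj=st.floats(-5, 5), dk=st.floats(-5, 5),
           w=st.floats(0.01, 100))
    @settings(max_examples=100, deadline=None)
    def test_linear_in_weight(self, di, dj, dk, w):
        e1 = ms.triangle_energy(di, dj, dk, w)
        e2 = ms.triangle_energy(di, dj, dk, 2 * w)
        assert e2 == pytest.approx(2 * e1, rel=1e-12, abs=1e-12)


class TestMrfLogPrior:
    def test_constant_field_has_zero_energy(self, icosahedron):
        cfg = ms.MRFConfig(weight=10.0)
        assert ms.mrf_log_prior(np.full(12, 1.7), icosahedron, cfg) == 0.0

    def test_invariant_to_global_shift(self, icosahedron):
        rng = np.random.default_rng(0)
        d = rng.normal(size=12)
        cfg = ms.MRFConfig(weight=3.0)
        a = ms.mrf_log_prior(d, icosahedron, cfg)
        b = ms.mrf_log_prior(d + 4.2, icosahedron, cfg)
        assert a == pytest.approx(b, rel=1e-10)
        assert a <= 0.0

    def test_matches_per_triangle_loop_oracle(self, icosahedron):
        rng = np.random.default_rng(1)
        d = rng.normal(size=12)
        cfg = ms.MRFConfig(weight=7.0)
        total = sum(ms.triangle_energy(d[i], d[j], d[k], cfg.weight)
                    for i, j, k in icosahedron.faces)
        assert ms.mrf_log_prior(d, icosahedron, cfg) == pytest.approx(-total)

    def test_length_mismatch_raises(self, icosahedron):
        with pytest.raises(MeshSegError):
            ms.mrf_log_prior(np.zeros(5), icosahedron, ms.MRFConfig())


def random_smooth_likelihood(mesh, grid, rng):
    """Log-likelihood tables from the model's operating regime: Gaussian-
    shaped in the displacement, centred on a smooth field plus noise."""
    mu = mesh.vertices @ rng.normal(0, 0.7, 3) + rng.normal(0, 0.5, mesh.n_vertices)
    s = rng.uniform(0.5, 1.0)
    ll = -(grid[None, :] - mu[:, None]) ** 2 / (2 * s ** 2)
    return ll - ll.max(axis=1, keepdims=True)


class TestICM:
    def test_zero_weight_reduces_to_pointwise_argmax(self, icosahedron):
        rng = np.random.default_rng(2)
        grid = np.array([-1.0, 0.0, 1.0])
        for _ in range(10):
            lik = np.log(rng.dirichlet(np.ones(3), size=12))
            out = ms.icm_optimize(lik, icosahedron, ms.MRFConfig(weight=0.0),
                                  grid=grid)
            assert np.array_equal(np.searchsorted(grid, out.values),
                                  lik.argmax(axis=1))

    def test_unanimous_likelihood_converges_in_one_sweep(self, icosahedron):
        grid = np.array([-1.0, 0.0, 1.0])
        lik = np.full((12, 3), -10.0)
        lik[:, 2] = -0.1
        out = ms.icm_optimize(lik, icosahedron, ms.MRFConfig(weight=5.0), grid=grid)
        assert np.all(out.values == 1.0)
        assert out.sweeps == 1
        assert out.converged

    def test_energy_never_increases_at_any_update(self, icosahedron):
        rng = np.random.default_rng(3)
        grid = np.linspace(-1, 1, 5)
        for _ in range(20):
            lik = random_smooth_likelihood(icosahedron, grid, rng)
            out = ms.icm_optimize(lik, icosahedron, ms.MRFConfig(weight=2.0),
                                  grid=grid)
            assert np.all(out.energy_deltas <= 1e-12)

    def test_matches_exhaustive_search_on_octahedron(self):
        verts = np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0],
                          [0, 0, 1], [0, 0, -1]], float)
        faces = np.array([[0, 2, 4], [2, 1, 4], [1, 3, 4], [3, 0, 4],
                          [2, 0, 5], [1, 2, 5], [3, 1, 5], [0, 3, 5]])
        mesh = ms.TriangleMesh(verts, faces).with_normals()
        grid = np.array([-1.0, 0.0, 1.0])
        rng = np.random.default_rng(4)
        cfg = ms.MRFConfig(weight=10.0)
        digits = np.array(np.meshgrid(*[range(3)] * 6, indexing="ij")).reshape(6, -1).T
        match = 0
        n_inst = 25
        for _ in range(n_inst):
            lik = random_smooth_likelihood(mesh, grid, rng)
            energies = np.array([
                ms.posterior_energy(d, lik, mesh, cfg, grid) for d in digits])
            best = energies.min()
            out = ms.icm_optimize(lik, mesh, cfg, grid=grid)
            e = ms.posterior_energy(np.searchsorted(grid, out.values), lik,
                                    mesh, cfg, grid)
            assert e >= best - 1e-9  # ICM can never beat the global optimum
            if e <= best + 1e-9:
                match += 1
        assert match / n_inst >= 0.9

    def test_invariant_under_vertex_relabeling(self, icosahedron):
        rng = np.random.default_rng(5)
        grid = np.linspace(-1, 1, 5)
        lik = random_smooth_likelihood(icosahedron, grid, rng)
        cfg = ms.MRFConfig(weight=2.0)
        out = ms.icm_optimize(lik, icosahedron, cfg, grid=grid)
        perm = rng.permutation(12)
        inv = np.empty(12, int)
        inv[perm] = np.arange(12)
        permuted = ms.TriangleMesh(icosahedron.vertices[perm],
                                   inv[icosahedron.faces]).with_normals()
        out_p = ms.icm_optimize(lik[perm], permuted, cfg, grid=grid)
        assert np.allclose(out_p.values, out.values[perm])

    def test_stronger_weight_reduces_field_variance(self, icosahedron):
        """Larger MRF weight smooths the output field. ICM's local optima can
        break strict per-instance monotonicity across a weight grid, so the
        check is: every weighted solution is no rougher than the
        likelihood-only one, and the mean variance over instances decreases
        weakly along the weight grid."""
        rng = np.random.default_rng(6)
        grid = np.linspace(-1, 1, 5)
        weights = [0.0, 0.5, 2.0, 10.0, 100.0]
        all_vars = []
        for _ in range(10):
            lik = random_smooth_likelihood(icosahedron, grid, rng)
            variances = [
                np.var(ms.icm_optimize(lik, icosahedron, ms.MRFConfig(weight=w),
                                       grid=grid).values)
                for w in weights
            ]
            assert all(v <= variances[0] + 1e-12 for v in variances)
            all_vars.append(variances)
        mean_vars = np.mean(all_vars, axis=0)
        assert all(b <= a + 1e-12 for a, b in zip(mean_vars, mean_vars[1:]))

    def test_nonfinite_likelihood_rejected(self, icosahedron):
        lik = np.zeros((12, 3))
        lik[3, 1] = np.nan
        with pytest.raises(MeshSegError, match="vertex 3"):
            ms.icm_optimize(lik, icosahedron, ms.MRFConfig(), grid=np.arange(3.))


class TestSegmentStructure:
    def test_phantom_recovery(self, phantom_study):
        two_steps = 2 * phantom_study["sampling"].step_mm
        for subj, res in phantom_study["test_results"]:
            truth = subj["truths"]["nucleus"]
            assert ms.dice_score(res.mask, truth.mask) >= 0.85
            dtrue = ms.truth_displacements(truth, phantom_study["ref_mesh"])
            assert np.mean(np.abs(res.displacements.values - dtrue)) <= two_steps
            assert res.report["converged"]

    def test_reference_on_truth_boundary_yields_small_displacements(self, phantom_study):
        subj, _ = phantom_study["test_results"][0]
        model = phantom_study["model"]
        sampling = phantom_study["sampling"]
        # the model was trained per-vertex on the reference mesh; resample its
        # learned appearance by segmenting with the truth mesh as the start
        truth = subj["truths"]["nucleus"]
        # vertex counts differ between truth and reference meshes, so restrict
        # to the displacement-level self-consistency check via the reference
        res = ms.segment_structure(subj["volumes"], model,
                                   phantom_study["ref_mesh"],
                                   ms.MRFConfig(weight=10.0))
        moved = res.mesh
        res2 = ms.segment_structure(subj["volumes"], model, moved,
                                    ms.MRFConfig(weight=10.0))
        assert abs(np.mean(res2.displacements.values)) <= sampling.step_mm
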