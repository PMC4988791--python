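"""EM training of the edge-appearance model and displacement posteriors."""

import numpy as np
import pytest

import meshseg as ms
from meshseg.errors import ModelError
from meshseg.model import train_intensity_model_from_profiles


@pytest.fixture(scope="module")
def cfg():
    return ms.ProfileSamplingConfig.from_voxel_size(0.5)


def make_training_setup(cfg, n_vertices=25, n_subjects=20, noise_sd=0.01, seed=0,
                        shifts=None):
    """Profiles generated from the step template of a two-component rule set
    (step + slow exponential), optionally shifted per subject."""
    rules = {"qsm": [ms.PriorRule("qsm", "step", 0.1, 0.0),
                     ms.PriorRule("qsm", "exponential", 0.1, 0.0, scales_mm=(3.0,))]}
    mods = [ms.ModalityConfig("qsm", prior_sd=0.0003, normalization="absolute")]
    true_t = ms.build_edge_templates(rules["qsm"][:1], cfg, smoothness_sd=0.5)[0]
    rng = np.random.default_rng(seed)
    Y = np.empty((n_vertices, n_subjects, cfg.k))
    for s in range(n_subjects):
        t = true_t
        if shifts is not None:
            t = np.roll(true_t, shifts[s])
        Y[:, s, :] = t[None, :] + rng.normal(0, noise_sd, (n_vertices, cfg.k))
    return Y, rules, mods, true_t


class TestTraining:
    def test_single_template_recovery(self, cfg):
        Y, rules, mods, true_t = make_training_setup(cfg)
        model = train_intensity_model_from_profiles({"qsm": Y}, rules, mods, cfg)
        W = model.weights["qsm"]
        assert np.all(W[:, 0] > 0.9)  # generating component dominates
        resid_sd = 1.0 / np.sqrt(model.precisions["qsm"][:, 0, :])
        assert np.all(np.abs(model.means["qsm"][:, 0, :] - true_t) < 2 * resid_sd)

    def test_log_posterior_nondecreasing(self, cfg):
        Y, rules, mods, _ = make_training_setup(cfg, noise_sd=0.02, seed=3)
        model = train_intensity_model_from_profiles({"qsm": Y}, rules, mods, cfg)
        tr = np.array(model.log_posterior_trace)
        assert len(tr) >= 2
        assert np.all(np.diff(tr) >= -1e-8 * (np.abs(tr[:-1]) + 1.0))

    def test_huge_prior_weight_pins_means_to_template(self, cfg):
        Y, rules, mods, _ = make_training_setup(cfg, n_subjects=3, noise_sd=0.05)
        hyper = ms.ModelHyperparams(n0=1e6)
        model = train_intensity_model_from_profiles({"qsm": Y}, rules, mods, cfg,
                                                    hyper)
        for c in range(model.prior_templates["qsm"].shape[0]):
            assert np.all(np.abs(model.means["qsm"][:, c, :]
                                 - model.prior_templates["qsm"][c]) < 1e-3)

    def test_mixture_weight_recovery_from_mixed_data(self, cfg):
        """Profiles simulated from the model with a 50/50 component mixture:
        the learned weights, averaged over vertices, land within 0.1 of the
        generating proportions (per-vertex estimates carry ~0.11 binomial
        noise at 20 subjects, so the check is on the mean)."""
        rules = {"qsm": [ms.PriorRule("qsm", "step", 0.1, 0.0),
                         ms.PriorRule("qsm", "exponential", 0.1, 0.0,
                                      scales_mm=(3.0,))]}
        mods = [ms.ModalityConfig("qsm", prior_sd=0.0003,
                                  normalization="absolute")]
        temps = ms.build_edge_templates(rules["qsm"], cfg, smoothness_sd=0.5)
        rng = np.random.default_rng(11)
        V, S = 40, 20
        comp = rng.integers(0, 2, size=(V, S))
        Y = temps[comp] + rng.normal(0, 0.01, (V, S, cfg.k))
        model = train_intensity_model_from_profiles({"qsm": Y}, rules, mods, cfg)
        W = model.weights["qsm"].mean(axis=0)
        assert abs(W[0] - 0.5) < 0.1
        assert abs(W[1] - 0.5) < 0.1
        assert W[2] < 0.15  # flat component stays small

    def test_too_few_subjects_rejected(self, cfg):
        Y, rules, mods, _ = make_training_setup(cfg, n_subjects=1)
        with pytest.raises(ModelError):
            train_intensity_model_from_profiles({"qsm": Y}, rules, mods, cfg)


@pytest.fixture(scope="module")
def trained(cfg):
    Y, rules, mods, true_t = make_training_setup(cfg)
    model = train_intensity_model_from_profiles({"qsm": Y}, rules, mods, cfg)
    return model, true_t


class TestDisplacementPosterior:
    def test_rows_are_normalized(self, trained, cfg):
        model, true_t = trained
        V = model.n_vertices
        lp = ms.displacement_posterior(model, {"qsm": np.tile(true_t, (V, 1))})
        assert np.allclose(np.exp(lp).sum(axis=1), 1.0, atol=1e-9)

    def test_unshifted_template_peaks_at_zero(self, trained, cfg):
        model, true_t = trained
        V = model.n_vertices
        lp = ms.displacement_posterior(model, {"qsm": np.tile(true_t, (V, 1))})
        assert np.all(cfg.displacement_grid[lp.argmax(axis=1)] == 0.0)

    @pytest.mark.parametrize("shift", [-2, -1, 1, 2])
    def test_shift_equivariance(self, trained, cfg, shift):
        model, true_t = trained
        V = model.n_vertices
        obs = np.tile(np.roll(true_t, shift), (V, 1))
        lp = ms.displacement_posterior(model, {"qsm": obs})
        expected = shift * cfg.step_mm
        frac = np.mean(cfg.displacement_grid[lp.argmax(axis=1)] == expected)
        assert frac >= 0.95

    def test_flat_profile_at_inside_level_pushes_edge_out_of_window(self, trained, cfg):
        # a profile that is at the inside value everywhere means the boundary
        # was not reached: the best grid estimate is the largest displacement
        model, _ = trained
        V = model.n_vertices
        flat = np.full((V, cfg.k), 0.1)
        lp = ms.displacement_posterior(model, {"qsm": flat})
        assert np.all(cfg.displacement_grid[lp.argmax(axis=1)]
                      == cfg.displacement_grid[-1])

    def test_no_edge_profile_defers_to_displacement_prior(self, trained, cfg):
        # a profile matching the flat no-edge component carries no boundary
        # information; the shift-invariant component wins and the symmetric
        # displacement prior puts the argmax at 0
        model, _ = trained
        V = model.n_vertices
        level = float(model.prior_templates["qsm"][-1, 0])
        flat = np.full((V, cfg.k), level)
        lp = ms.displacement_posterior(model, {"qsm": flat})
        assert np.all(cfg.displacement_grid[lp.argmax(axis=1)] == 0.0)

    def test_untrained_model_rejected(self, cfg):
        model = ms.IntensityModel(config=cfg, modalities=[], rules={},
                                  hyper=ms.ModelHyperparams())
        with pytest.raises(ModelError):
            ms.displacement_posterior(model, {})


class TestMultimodalWeighting:
    def test_low_noise_modality_dominates(self, cfg):
        """Two modalities disagree on the displacement; the one with ~100x
        smaller residual sd must decide the grid argmax."""
        rules = {
            "sharp": [ms.PriorRule("sharp", "step", 0.1, 0.0)],
            "blurry": [ms.PriorRule("blurry", "step", 1.0, 1.33)],
        }
        mods = [ms.ModalityConfig("sharp", prior_sd=0.0003, normalization="absolute"),
                ms.ModalityConfig("blurry", prior_sd=0.1, normalization="absolute")]
        t_sharp = ms.build_edge_templates(rules["sharp"], cfg, smoothness_sd=0.5)[0]
        t_blur = ms.build_edge_templates(rules["blurry"], cfg, smoothness_sd=0.5)[0]
        rng = np.random.default_rng(1)
        V, S = 20, 20
        Y = {
            "sharp": t_sharp[None, None] + rng.normal(0, 0.001, (V, S, cfg.k)),
            "blurry": t_blur[None, None] + rng.normal(0, 0.1, (V, S, cfg.k)),
        }
        model = train_intensity_model_from_profiles(Y, rules, mods, cfg)
        # observed: sharp says +2 steps, blurry says -2 steps
        obs = {"sharp": np.tile(np.roll(t_sharp, 2), (V, 1)),
               "blurry": np.tile(np.roll(t_blur, -2), (V, 1))}
        lp = ms.displacement_posterior(model, obs)
        single = ms.displacement_posterior(
            model_single(model, "sharp"), {"sharp": obs["sharp"]})
        assert np.array_equal(lp.argmax(axis=1), single.argmax(axis=1))


def model_single(model, name):
    """Restriction of a trained model to one modality (for oracle tests)."""
    import copy
    out = copy.copy(model)
    out.modalities = [m for m in model.modalities if m.name == name]
    return out
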