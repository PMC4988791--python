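"""Edge-appearance model: EM training and displacement posteriors.

Each vertex of the reference mesh carries, per modality, a mixture of edge
templates describing the intensity profile expected across the structure
boundary. The mixture components are the rule-based prior templates (step or
exponential edges at one or more decay scales) plus one flat "no-edge"
component. Training is unsupervised: given profiles sampled around the
roughly aligned reference mesh in a set of unlabelled subjects, an EM
algorithm estimates, per vertex and modality,

* the component mean profiles (Normal, with the rule template as a conjugate
  prior mean carrying ``n0`` pseudo-observations),
* diagonal per-sample precisions (Gamma prior with shape ``alpha0`` and a
  rate fixed by the modality's prior standard deviation), and
* mixture weights (Dirichlet prior, parameter ``alpha`` for all components),

marginalizing over the unknown per-subject boundary displacement, which is
shared across modalities and carries a Gaussian prior of width
``sigma_delta``. The E-step computes joint responsibilities over
(component, displacement); the M-step performs exact MAP updates, so the
log-posterior is non-decreasing across iterations.

At segmentation time the same machinery inverts: given observed profiles for
a new subject, :func:`displacement_posterior` returns, per vertex, the
normalized log-posterior over the discrete displacement grid, combining
modalities by log-addition (conditional independence given the
displacement). A modality whose learned residual precision is high is
thereby automatically weighted more strongly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .errors import ModelError
from .profiles import ModalityConfig, PriorRule, ProfileSamplingConfig, build_edge_templates

__all__ = [
    "ModelHyperparams",
    "IntensityModel",
    "train_intensity_model",
    "train_intensity_model_from_profiles",
    "displacement_posterior",
]


@dataclass(frozen=True)
class ModelHyperparams:
    """Scalar hyperparameters of the intensity model.

    n0: pseudo-observation weight of the prior mean profile (3).
    dirichlet_alpha: Dirichlet parameter for all mixture components (2).
    sigma_delta_mm: width of the Gaussian prior on the boundary displacement (2 mm).
    smoothness_sd: Gaussian blur (in samples) applied to prior templates (0.5).
    wishart_shape: Gamma/Wishart shape for the precisions; None means the
        default (k - 1)/2 + 3 tied to the profile length.
    max_iter / tol: EM iteration cap and relative log-posterior tolerance.
    """

    n0: float = 3.0
    dirichlet_alpha: float = 2.0
    sigma_delta_mm: float = 2.0
    smoothness_sd: float = 0.5
    wishart_shape: float | None = None
    max_iter: int = 100
    tol: float = 1e-6

    def shape_for(self, k: int) -> float:
        return self.wishart_shape if self.wishart_shape is not None else (k - 1) / 2.0 + 3.0


@dataclass
class IntensityModel:
    """Trained per-vertex, per-modality edge-appearance model."""

    config: ProfileSamplingConfig
    modalities: list  # list[ModalityConfig]
    rules: dict  # modality name -> list[PriorRule]
    hyper: ModelHyperparams
    prior_templates: dict = field(default_factory=dict)  # name -> (C, k)
    means: dict = field(default_factory=dict)  # name -> (V, C, k)
    precisions: dict = field(default_factory=dict)  # name -> (V, C, k)
    weights: dict = field(default_factory=dict)  # name -> (V, C)
    log_posterior_trace: list = field(default_factory=list)
    trained: bool = False

    @property
    def n_vertices(self) -> int:
        if not self.means:
            raise ModelError("model is untrained")
        return next(iter(self.means.values())).shape[0]

    def modality(self, name: str) -> ModalityConfig:
        for m in self.modalities:
            if m.name == name:
                return m
        raise ModelError(f"unknown modality {name!r}")


# ---------------------------------------------------------------------------
# Shift bookkeeping
# ---------------------------------------------------------------------------


def _shift_index(k: int) -> np.ndarray:
    """Template index used for sample j under displacement step n.

    Returns an (n_shifts, k) int array G with G[d, j] = clip(j - n_d, 0, k-1)
    where n_d runs over the displacement grid steps (-k//2 .. +k//2). A
    positive displacement moves the boundary outward, so the observed profile
    is the template translated toward positive s; indices clamp at the
    plateau ends of the template.
    """
    half = (k - 1) // 2
    n = np.arange(-half, half + 1)
    j = np.arange(k)
    return np.clip(j[None, :] - n[:, None], 0, k - 1)


def _log_delta_prior(config: ProfileSamplingConfig, sigma_delta: float) -> np.ndarray:
    """Normalized log-prior over the discrete displacement grid."""
    delta = config.displacement_grid
    lp = -0.5 * (delta / sigma_delta) ** 2
    return lp - logsumexp(lp)


def _component_loglik(Y: np.ndarray, M: np.ndarray, P: np.ndarray,
                      G: np.ndarray) -> np.ndarray:
    """Per-(vertex, subject, component, displacement) Gaussian log-likelihood.

    Y: (V, S, k) observed profiles; M, P: (V, C, k) means/precisions in the
    template frame; G: (D, k) shift gather indices. Returns (V, S, C, D).
    """
    V, S, k = Y.shape
    C = M.shape[1]
    D = G.shape[0]
    out = np.empty((V, S, C, D))
    const = -0.5 * np.log(2.0 * np.pi)
    for d in range(D):
        g = G[d]
        Mg = M[:, :, g]  # (V, C, k)
        Pg = P[:, :, g]
        # (V, S, C, k) residuals via broadcasting, reduced over k
        r2 = (Y[:, :, None, :] - Mg[:, None, :, :]) ** 2
        out[:, :, :, d] = (
            0.5 * np.log(Pg).sum(axis=2)[:, None, :]
            + k * const
            - 0.5 * np.einsum("vsck,vck->vsc", r2, Pg)
        )
    return out


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


def _init_modality(V: int, rules, modality: ModalityConfig,
                   config: ProfileSamplingConfig, hyper: ModelHyperparams):
    """Prior templates (with the flat no-edge component appended) and the
    deterministic initialization at the prior."""
    self_value = 1.0 if modality.normalization == "relative" else None
    base = build_edge_templates(rules, config, self_value=self_value,
                                smoothness_sd=hyper.smoothness_sd)
    flat = np.full((1, config.k), base.mean())
    T0 = np.vstack([base, flat])  # (C, k)
    C = len(T0)
    M = np.broadcast_to(T0, (V, C, config.k)).copy()
    P = np.full((V, C, config.k), 1.0 / modality.prior_sd ** 2)
    W = np.full((V, C), 1.0 / C)
    return T0, M, P, W


def _param_log_prior(T0, M, P, W, modality: ModalityConfig, hyper: ModelHyperparams, k: int):
    """Parameter-dependent part of the log prior on (means, precisions, weights)."""
    a0 = hyper.shape_for(k)
    b0 = a0 * modality.prior_sd ** 2
    lp = 0.5 * np.log(hyper.n0 * P).sum()
    lp -= 0.5 * hyper.n0 * (P * (M - T0[None]) ** 2).sum()
    lp += ((a0 - 1.0) * np.log(P) - b0 * P).sum()
    lp += (hyper.dirichlet_alpha - 1.0) * np.log(W).sum()
    return float(lp)


def train_intensity_model_from_profiles(
    profiles: dict,
    rules: dict,
    modalities: list,
    config: ProfileSamplingConfig,
    hyper: ModelHyperparams = ModelHyperparams(),
) -> IntensityModel:
    """Train the edge-appearance model from pre-sampled profiles.

    Parameters
    ----------
    profiles : dict mapping modality name -> (V, S, k) array of observed
        profiles (already normalized for relative modalities), with V
        vertices, S training subjects, k samples.
    rules : dict mapping modality name -> list of PriorRule.
    modalities : list of ModalityConfig (order defines modality order).
    """
    names = [m.name for m in modalities]
    shapes = {n: np.asarray(profiles[n], float) for n in names}
    V, S, k = shapes[names[0]].shape
    if S < 2:
        raise ModelError("training requires at least 2 subjects")
    if k != config.k:
        raise ModelError(f"profile length {k} != sampling config k={config.k}")
    for n in names:
        if shapes[n].shape != (V, S, k):
            raise ModelError("all modalities must share (V, S, k)")

    G = _shift_index(k)
    D = G.shape[0]
    log_pd = _log_delta_prior(config, hyper.sigma_delta_mm)
    a0 = hyper.shape_for(k)

    state = {}
    for m in modalities:
        T0, M, P, W = _init_modality(V, rules[m.name], m, config, hyper)
        state[m.name] = dict(T0=T0, M=M, P=P, W=W)

    # gather counts: for template index i, how many sample positions map to it
    # under each displacement (used to scatter statistics back exactly)
    trace = []
    prev = -np.inf
    for it in range(hyper.max_iter):
        # ---- E-step ----
        LL = {}
        A = np.zeros((V, S, D))
        for m in modalities:
            st = state[m.name]
            ll = _component_loglik(shapes[m.name], st["M"], st["P"], G)
            ll = ll + np.log(st["W"])[:, None, :, None]
            LL[m.name] = ll
            A += logsumexp(ll, axis=2)  # marginalize component
        logq_d = log_pd[None, None, :] + A  # (V, S, D)
        norm = logsumexp(logq_d, axis=2)  # (V, S) per-datum marginal loglik
        if not np.all(np.isfinite(norm)):
            v, s = np.argwhere(~np.isfinite(norm))[0]
            raise ModelError(f"non-finite log-posterior at vertex {v}, subject {s}")
        logq_d = logq_d - norm[:, :, None]

        obj = float(norm.sum())
        for m in modalities:
            st = state[m.name]
            obj += _param_log_prior(st["T0"], st["M"], st["P"], st["W"], m, hyper, k)
        trace.append(obj)

        # ---- M-step ----
        for m in modalities:
            st = state[m.name]
            ll = LL[m.name]
            logq_c = ll - logsumexp(ll, axis=2, keepdims=True)  # p(c | d, y)
            R = np.exp(logq_c + logq_d[:, :, None, :])  # (V, S, C, D)
            Y = shapes[m.name]
            C = st["M"].shape[1]
            Nc = R.sum(axis=(1, 3))  # (V, C)

            # scatter sufficient statistics into the template frame
            S0 = np.zeros((V, C, k))
            S1 = np.zeros((V, C, k))
            S2 = np.zeros((V, C, k))
            for d in range(D):
                g = G[d]
                w_vd = R[:, :, :, d]  # (V, S, C)
                wy = np.einsum("vsc,vsj->vcj", w_vd, Y)
                wy2 = np.einsum("vsc,vsj->vcj", w_vd, Y ** 2)
                wsum = w_vd.sum(axis=1)  # (V, C)
                for j in range(k):
                    S0[:, :, g[j]] += wsum
                    S1[:, :, g[j]] += wy[:, :, j]
                    S2[:, :, g[j]] += wy2[:, :, j]

            n0 = hyper.n0
            T0 = st["T0"][None]
            M = (n0 * T0 + S1) / (n0 + S0)
            SS = S2 - 2.0 * M * S1 + S0 * M ** 2
            SS = np.maximum(SS, 0.0)
            b0 = a0 * m.prior_sd ** 2
            P = (a0 - 1.0 + 0.5 * (S0 + 1.0)) / (b0 + 0.5 * (SS + n0 * (M - T0) ** 2))
            alpha = hyper.dirichlet_alpha
            W = (Nc + alpha - 1.0)
            W = W / W.sum(axis=1, keepdims=True)
            W = np.maximum(W, 1e-12)
            W = W / W.sum(axis=1, keepdims=True)
            st.update(M=M, P=P, W=W)

        if it > 0 and abs(trace[-1] - prev) <= hyper.tol * (abs(prev) + 1.0):
            prev = trace[-1]
            break
        prev = trace[-1]

    model = IntensityModel(
        config=config, modalities=list(modalities), rules=dict(rules), hyper=hyper,
        prior_templates={n: state[n]["T0"] for n in names},
        means={n: state[n]["M"] for n in names},
        precisions={n: state[n]["P"] for n in names},
        weights={n: state[n]["W"] for n in names},
        log_posterior_trace=trace, trained=True,
    )
    return model


def train_intensity_model(
    subject_volumes: list,
    reference_mesh,
    rules: dict,
    modalities: list,
    config: ProfileSamplingConfig,
    hyper: ModelHyperparams = ModelHyperparams(),
    transforms: list | None = None,
) -> IntensityModel:
    """Train the edge-appearance model from unlabelled subject volumes.

    Parameters
    ----------
    subject_volumes : list (one entry per training subject) of dicts mapping
        modality name -> (data, affine); modalities must be co-registered
        within each subject.
    reference_mesh : the structure's reference mesh.
    transforms : optional per-subject transforms mapping reference space to
        subject space (4x4 affines or callables); identity if None.

    For every subject the reference mesh is mapped into subject space,
    perpendicular profiles are sampled at its vertices, relative modalities
    are divided by the subject's modal structure intensity ("Self", measured
    inside the mapped mesh), and the stacked profiles are handed to the EM
    trainer.
    """
    from .mesh import VoxelMask, mesh_to_mask  # local import avoids a cycle
    from .profiles import sample_profiles
    from .transforms import apply_to_mesh

    if len(subject_volumes) < 2:
        raise ModelError("training requires at least 2 subjects")
    if transforms is None:
        transforms = [None] * len(subject_volumes)
    if len(transforms) != len(subject_volumes):
        raise ModelError("one transform per training subject required")

    names = [m.name for m in modalities]
    per_mod = {n: [] for n in names}
    for volumes, transform in zip(subject_volumes, transforms):
        mesh = apply_to_mesh(transform, reference_mesh)
        region = None
        for m in modalities:
            data, affine = volumes[m.name]
            prof = sample_profiles(data, affine, mesh.vertices, mesh.normals, config)
            if m.normalization == "relative":
                if region is None:
                    grid_like = VoxelMask(np.zeros(np.asarray(data).shape, bool), affine)
                    region = mesh_to_mask(mesh, grid_like)
                from .profiles import modal_intensity
                sv = modal_intensity(data, region)
                if abs(sv) < 1e-12:
                    raise ModelError(f"modal intensity ~0 for modality {m.name!r}")
                prof = prof / sv
            per_mod[m.name].append(prof)
    profiles = {n: np.stack(per_mod[n], axis=1) for n in names}  # (V, S, k)
    return train_intensity_model_from_profiles(profiles, rules, modalities,
                                               config, hyper)


# ---------------------------------------------------------------------------
# Displacement posterior
# ---------------------------------------------------------------------------


def displacement_posterior(model: IntensityModel, profiles: dict) -> np.ndarray:
    """Per-vertex normalized log-posterior over the displacement grid.

    ``profiles`` maps modality name -> (V, k) observed profiles (normalized
    for relative modalities). Modalities combine by log-addition; the
    Gaussian displacement prior of width sigma_delta is included. Each output
    row exponentiates and sums to one.
    """
    if not model.trained:
        raise ModelError("displacement_posterior requires a trained model")
    k = model.config.k
    G = _shift_index(k)
    V = model.n_vertices
    log_pd = _log_delta_prior(model.config, model.hyper.sigma_delta_mm)
    total = np.tile(log_pd, (V, 1))
    for m in model.modalities:
        Y = np.asarray(profiles[m.name], float)
        if Y.shape != (V, k):
            raise ModelError(
                f"profiles for {m.name!r} must be ({V}, {k}), got {Y.shape}")
        ll = _component_loglik(Y[:, None, :], model.means[m.name],
                               model.precisions[m.name], G)[:, 0]  # (V, C, D)
        ll = ll + np.log(model.weights[m.name])[:, :, None]
        total += logsumexp(ll, axis=1)
    total -= logsumexp(total, axis=1, keepdims=True)
    return total
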