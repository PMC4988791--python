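"""Intensity profiles, rule-based edge templates and modal intensities.

The segmentation method detects a structure boundary by sampling short 1D
intensity profiles perpendicular to a roughly aligned mesh and matching them
against learned edge-appearance templates. This module implements the
sampling geometry, the rule-based construction of the prior templates
(step-edge and exponentially decaying edge families), and the modal-intensity
statistic used as the structure's representative "Self" intensity.

Sampling geometry: with step size ``l`` (mm, half a voxel by default) and an
even number of steps ``n_steps`` (chosen so the profile spans +/- 2 mm), the
``k = n_steps + 1`` sample positions are ``s_j = (j - n_steps/2) * l``,
symmetric about the boundary at s = 0. Negative s is inside the structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import EmptyMaskError, MeshSegError, ProfileOutOfBoundsError
from .mesh import VoxelMask

__all__ = [
    "ProfileSamplingConfig",
    "PriorRule",
    "ModalityConfig",
    "sample_profile",
    "sample_profiles",
    "modal_intensity",
    "build_edge_templates",
]


@dataclass(frozen=True)
class ProfileSamplingConfig:
    """Geometry of the perpendicular intensity profiles.

    Parameters
    ----------
    step_mm : profile step size ``l`` in mm (half the voxel size by default).
    n_steps : even number of steps; the profile has ``n_steps + 1`` samples
        spanning ``+/- n_steps/2 * step_mm`` around the boundary. The default
        rule is ``n_steps = 2 * ceil(2 mm / step_mm)`` so the profile covers
        +/- 2 mm.
    """

    step_mm: float
    n_steps: int

    def __post_init__(self):
        if self.step_mm <= 0:
            raise MeshSegError("step_mm must be positive")
        if self.n_steps <= 0 or self.n_steps % 2 != 0:
            raise MeshSegError("n_steps must be a positive even integer")

    @classmethod
    def from_voxel_size(cls, voxel_mm: float, extent_mm: float = 2.0) -> "ProfileSamplingConfig":
        """Step size = half the voxel size; span +/- `extent_mm`."""
        step = voxel_mm / 2.0
        n_steps = 2 * int(round(extent_mm / step))
        return cls(step_mm=step, n_steps=n_steps)

    @property
    def k(self) -> int:
        """Number of samples per profile."""
        return self.n_steps + 1

    @property
    def positions(self) -> np.ndarray:
        """Sample positions s_j (mm) along the outward normal; s=0 is the
        nominal boundary, negative s inside."""
        j = np.arange(self.k)
        return (j - self.n_steps / 2.0) * self.step_mm

    @property
    def displacement_grid(self) -> np.ndarray:
        """The discrete displacement candidates: the same grid as the sample
        positions (the likelihood is only evaluated where profiles exist)."""
        return self.positions


@dataclass(frozen=True)
class PriorRule:
    """One row of the rule table that sets up an edge-appearance prior.

    ``template`` is "step" or "exponential"; exponential rules carry one or
    more decay scales (mm). Inside/outside intensities may be absolute
    numbers, the modal structure intensity ("self"), or a multiple of it
    ("self*1.33").
    """

    modality: str
    template: str  # "step" | "exponential"
    inside: float | str
    outside: float | str
    scales_mm: tuple = ()

    def __post_init__(self):
        if self.template not in ("step", "exponential"):
            raise MeshSegError(f"unknown template type {self.template!r}")
        if self.template == "exponential":
            if not self.scales_mm or any(s <= 0 for s in self.scales_mm):
                raise MeshSegError("exponential rule needs positive scales_mm")

    @staticmethod
    def _resolve(spec: float | str, self_value: float | None) -> float:
        if isinstance(spec, (int, float)):
            return float(spec)
        s = str(spec).strip().lower().replace(" ", "")
        if s == "self":
            factor = 1.0
        elif s.startswith("self*") or s.startswith("selfx"):
            factor = float(s[5:])
        else:
            return float(s)
        if self_value is None:
            raise MeshSegError("rule references Self but no self_value supplied")
        return factor * self_value

    def levels(self, self_value: float | None = None) -> tuple:
        """Resolved (inside, outside) intensity levels."""
        return (self._resolve(self.inside, self_value),
                self._resolve(self.outside, self_value))


@dataclass(frozen=True)
class ModalityConfig:
    """Per-modality configuration.

    ``prior_sd`` is the prior standard deviation on profile intensities
    (0.1 for T2*-like relative intensities, 0.0003 for QSM-like absolute
    susceptibility values). ``normalization`` is "relative" (profiles are
    divided by the subject's modal structure intensity, making the modality
    scale-free) or "absolute" (quantitative values used as-is).
    """

    name: str
    prior_sd: float
    normalization: str = "relative"

    def __post_init__(self):
        if self.prior_sd <= 0:
            raise MeshSegError("prior_sd must be positive")
        if self.normalization not in ("relative", "absolute"):
            raise MeshSegError("normalization must be 'relative' or 'absolute'")


# ---------------------------------------------------------------------------
# Profile sampling
# ---------------------------------------------------------------------------


def sample_profiles(volume: np.ndarray, affine: np.ndarray, points: np.ndarray,
                    normals: np.ndarray, config: ProfileSamplingConfig,
                    max_outside_fraction: float = 0.25) -> np.ndarray:
    """Sample perpendicular intensity profiles at many vertices at once.

    Returns an (n_points, k) array of trilinearly interpolated intensities at
    ``point + s_j * normal``. A vertex whose fraction of samples outside the
    field of view exceeds `max_outside_fraction` raises
    ProfileOutOfBoundsError (naming the first offending vertex); samples
    slightly outside are clamped to the nearest voxel.
    """
    points = np.atleast_2d(np.asarray(points, float))
    normals = np.atleast_2d(np.asarray(normals, float))
    s = config.positions  # (k,)
    # (n, k, 3) world sample locations
    locs = points[:, None, :] + s[None, :, None] * normals[:, None, :]
    inv = np.linalg.inv(np.asarray(affine, float))
    flat = locs.reshape(-1, 3)
    idx = (inv[:3, :3] @ flat.T).T + inv[:3, 3]
    shape = np.array(volume.shape, float)
    outside = np.any((idx < -0.5) | (idx > shape - 0.5), axis=1)
    out_frac = outside.reshape(len(points), config.k).mean(axis=1)
    bad = np.nonzero(out_frac > max_outside_fraction)[0]
    if bad.size:
        raise ProfileOutOfBoundsError(
            f"profile-out-of-bounds: vertex {bad[0]} has "
            f"{out_frac[bad[0]]:.0%} of samples outside the volume"
        )
    vals = ndimage.map_coordinates(np.asarray(volume, float), idx.T, order=1,
                                   mode="nearest")
    return vals.reshape(len(points), config.k)


def sample_profile(volume: np.ndarray, affine: np.ndarray, point: np.ndarray,
                   normal: np.ndarray, config: ProfileSamplingConfig) -> np.ndarray:
    """Single-vertex convenience wrapper around :func:`sample_profiles`."""
    return sample_profiles(volume, affine, point, normal, config)[0]


# ---------------------------------------------------------------------------
# Modal intensity
# ---------------------------------------------------------------------------


def modal_intensity(volume: np.ndarray, mask: VoxelMask, n_bins: int = 100) -> float:
    """Mode of the intensity histogram inside a mask.

    Binning: `n_bins` equal-width bins between the 1st and 99th percentile of
    the in-mask intensities (deterministic and robust to outliers); the mode
    is the center of the fullest bin. Degenerate (constant) regions return
    the constant.
    """
    if mask.count() == 0:
        raise EmptyMaskError("modal_intensity: empty mask")
    vals = np.asarray(volume, float)[mask.data]
    lo, hi = np.percentile(vals, [1.0, 99.0])
    if hi <= lo:
        return float(np.median(vals))
    counts, edges = np.histogram(vals, bins=n_bins, range=(lo, hi))
    i = int(np.argmax(counts))
    return float(0.5 * (edges[i] + edges[i + 1]))


# ---------------------------------------------------------------------------
# Rule-based edge templates
# ---------------------------------------------------------------------------


def _edge_shape(positions: np.ndarray, inside: float, outside: float,
                template: str, scale: float | None) -> np.ndarray:
    if template == "step":
        return np.where(positions < 0, inside, outside)
    # exponential approach to the outside level for s > 0
    out = np.full_like(positions, inside, dtype=float)
    pos = positions > 0
    out[pos] = inside + (outside - inside) * (1.0 - np.exp(-positions[pos] / scale))
    return out


def build_edge_templates(rules: list[PriorRule], config: ProfileSamplingConfig,
                         self_value: float | None = None,
                         smoothness_sd: float = 0.5) -> np.ndarray:
    """Construct the prior mean profiles from a rule list.

    Each rule contributes one template per decay scale (a rule with scales
    1 and 3 mm yields two mixture components). Step templates jump from the
    inside to the outside level at s = 0; exponential templates relax
    exponentially toward the outside level for s > 0. Every template is then
    blurred with a Gaussian of `smoothness_sd` (in sample units), modelling
    partial-volume blur at the boundary.

    Returns an (n_templates, k) array.
    """
    s = config.positions
    templates = []
    for rule in rules:
        inside, outside = rule.levels(self_value)
        scales = rule.scales_mm if rule.template == "exponential" else (None,)
        for lam in scales:
            t = _edge_shape(s, inside, outside, rule.template, lam)
            if smoothness_sd > 0:
                t = ndimage.gaussian_filter1d(t, smoothness_sd, mode="nearest")
            templates.append(t)
    if not templates:
        raise MeshSegError("no rules supplied")
    return np.array(templates)
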