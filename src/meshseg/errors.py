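"""Exception hierarchy for meshseg."""


class MeshSegError(Exception):
    """Base class for all meshseg errors."""


class ErosionEmptiedMaskError(MeshSegError):
    """Morphological erosion removed every voxel; supply a larger structure."""


class TopologyError(MeshSegError):
    """Extracted surface is not a single closed component."""

    def __init__(self, message: str, n_components: int | None = None):
        super().__init__(message)
        self.n_components = n_components


class ProfileOutOfBoundsError(MeshSegError):
    """Too many profile samples fall outside the imaged field of view."""


class EmptyMaskError(MeshSegError):
    """An operation that needs voxels received an empty mask."""


class ModelError(MeshSegError):
    """Intensity-model misuse (untrained model, non-finite objective, ...)."""


class DesignError(MeshSegError):
    """Invalid GLM design or contrast."""
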