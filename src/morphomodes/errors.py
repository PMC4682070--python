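"""Exception types shared across the pipeline."""


class MorphomodesError(Exception):
    """Base class for all package-specific errors."""


class DegenerateShapeError(MorphomodesError):
    """Raised for boundaries with zero perimeter or coincident points."""


class InvalidClusteringError(MorphomodesError):
    """Raised when a clustering has empty clusters or fails validity checks."""


class CapacityError(MorphomodesError):
    """Raised when a synthetic scene cannot place the requested cells."""


class RenderError(MorphomodesError):
    """Raised when boundaries fall outside the image to be rendered."""


class TileConflictError(MorphomodesError):
    """Raised when two tiles claim the same global pixel with different labels."""


class GatingError(MorphomodesError):
    """Raised when DNA-content gating cannot locate a G0/G1 peak."""


class SelectionError(MorphomodesError):
    """Raised when no candidate cluster count yields a valid clustering."""


class StageError(MorphomodesError):
    """Raised when a pipeline stage fails; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
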