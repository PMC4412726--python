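"""Exception hierarchy for petroi."""


class PetroiError(Exception):
    """Base class for all petroi-specific errors."""


class FormatError(PetroiError):
    """A file could not be read or is not a recognized volume/atlas format."""


class NormalizationError(PetroiError):
    """Intensity normalization failed (non-positive or non-finite reference mean)."""


class ConfigurationError(PetroiError):
    """Invalid user-supplied configuration (unknown region name, bad grid, ...)."""


class DegenerateComponentError(PetroiError):
    """A mixture component collapsed (vanishing total responsibility)."""


class GMMFitError(PetroiError):
    """EM failed for a given component count across all restarts."""


class SelectionError(PetroiError):
    """Model selection could not fit any candidate model."""


class EvaluationError(PetroiError):
    """Cross-validation workflow failed (degenerate folds, missing scores, ...)."""
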