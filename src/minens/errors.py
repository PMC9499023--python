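"""Exception hierarchy.

Every error raised on a user-facing contract violation derives from
:class:`MinensError`, so callers (and the CLI) can catch one base class.
"""


class MinensError(Exception):
    """Base class for all package errors."""


class InputError(MinensError):
    """Malformed user input (missing paths, mismatched vector lengths...)."""


class DatasetStructureError(MinensError):
    """Image-folder tree violates the one-directory-per-class layout."""


class ConfigError(MinensError):
    """Invalid configuration value or inconsistent option combination."""


class RegistryError(ConfigError):
    """Unknown backbone identifier."""


class PretrainedWeightsUnavailableError(RegistryError):
    """Pretrained initialization requested but no weights source is registered."""


class CheckpointError(MinensError):
    """Corrupt, missing, or incompatible checkpoint file."""


class ShapeError(MinensError):
    """Array with an unexpected spatial shape or channel count."""


class ChannelError(ShapeError):
    """Image is not 3-channel RGB."""


class NumericError(MinensError):
    """Numerically invalid operation (e.g. zero-variance normalization)."""


class LabelError(InputError):
    """Label index outside the valid class range."""


class DivergenceError(MinensError):
    """Training loss became non-finite."""

    def __init__(self, message: str, epoch: int | None = None):
        super().__init__(message)
        self.epoch = epoch


class SelectionError(MinensError):
    """Model selection asked for more candidates than exist."""
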