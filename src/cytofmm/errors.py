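"""Exception hierarchy shared across the package."""


class CytofmmError(Exception):
    """Base class for all package errors."""


class ShapeError(CytofmmError, ValueError):
    """Dimensionality or length mismatch between inputs."""


class InvalidInputError(CytofmmError, ValueError):
    """Input violates a documented precondition (empty, out of range...)."""


class ConfigError(CytofmmError, ValueError):
    """Unknown name or invalid value in a spec/config object."""


class ContractViolationError(CytofmmError, RuntimeError):
    """An operation was invoked when its precondition provably fails."""


class NotTrainedError(CytofmmError, RuntimeError):
    """Prediction requested from an empty / untrained model."""


class ExtractionError(CytofmmError, RuntimeError):
    """A feature-extraction adapter failed on a specific item."""

    def __init__(self, message: str, path: str | None = None):
        super().__init__(message if path is None else f"{message}: {path}")
        self.path = path
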