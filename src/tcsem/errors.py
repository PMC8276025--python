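"""Exception hierarchy shared across the package."""


class TcsemError(Exception):
    """Base class for all package-specific errors."""


class DimensionError(TcsemError, ValueError):
    """Shapes of videos, masks or measurements do not agree."""


class ParameterError(TcsemError, ValueError):
    """A scalar parameter is outside its legal range."""


class ProvenanceError(TcsemError, ValueError):
    """A measurement is paired with masks it was not produced from."""


class ConfigurationError(TcsemError, ValueError):
    """Network weights and configuration do not match."""


class StateError(TcsemError, ValueError):
    """A recurrent stage was invoked with missing or wrong prior state."""


class FormatError(TcsemError, ValueError):
    """An input file is not in a supported dialect."""


class TrainingError(TcsemError, RuntimeError):
    """Optimization diverged; carries diagnostic state."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}
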