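"""Exception hierarchy shared across the toolkit."""


class CSTError(Exception):
    """Base class for all toolkit errors."""


class FormatError(CSTError, ValueError):
    """A file could not be parsed in the expected on-disk format."""


class UnsupportedRateError(FormatError):
    """An EDF file mixes per-channel sampling rates, which is unsupported."""


class ParameterError(CSTError, ValueError):
    """A function argument is outside its admissible range."""


class ConfigurationError(CSTError, ValueError):
    """A model or run configuration is internally inconsistent."""


class DataError(CSTError, ValueError):
    """Input data violates a contract (shapes, labels, missing files)."""


class TrainingDivergedError(CSTError, RuntimeError):
    """The training loss became non-finite."""
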