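"""Exception hierarchy shared across the package."""


class PPGKitError(Exception):
    """Base class for all ppgkit errors."""


class InvalidParameterError(PPGKitError, ValueError):
    """A numeric parameter is out of its valid domain (degenerate rate, empty band, ...)."""


class ConfigurationError(PPGKitError, ValueError):
    """A configuration object is inconsistent (missing wavelength, unknown key, ...)."""


class InvalidInputError(PPGKitError, ValueError):
    """Input data violate a precondition (mismatched lengths, wrong sample rate, ...)."""


class FormatError(PPGKitError, ValueError):
    """A file could not be parsed (malformed header, ragged rows, unknown channel)."""


class DesignError(PPGKitError, RuntimeError):
    """A filter design procedure failed to converge."""


class UndefinedResultError(PPGKitError, RuntimeError):
    """The requested quantity is undefined for this input (too few beats, zero perfusion)."""
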