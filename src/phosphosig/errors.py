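"""Exception hierarchy shared across the pipeline stages."""


class PhosphosigError(Exception):
    """Base class for all errors raised by this package."""


class ConfigurationError(PhosphosigError, ValueError):
    """Invalid simulation or pipeline configuration."""


class FormatError(PhosphosigError, ValueError):
    """Malformed tabular input (bad header, ragged rows, non-numeric cells)."""


class ValidationError(PhosphosigError, ValueError):
    """Input table violates a contract (negative times, bad codes, ...)."""


class DegenerateDataError(PhosphosigError, ValueError):
    """Data admit no answer: constant probes, all-identical indices, ties."""


class ConvergenceError(PhosphosigError, RuntimeError):
    """A model fit failed to converge."""


class CollinearityError(PhosphosigError, ValueError):
    """Two covariates are (numerically) linearly dependent."""
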