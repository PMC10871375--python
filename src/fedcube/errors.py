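"""Exception hierarchy shared across the pipeline stages."""


class FedcubeError(Exception):
    """Base class for all pipeline errors."""


class ParseError(FedcubeError):
    """A line of an NDJSON file is not well-formed JSON."""


class ValidationError(FedcubeError):
    """A resource violates a structural precondition (e.g. wrong resourceType)."""


class ResolutionError(FedcubeError):
    """A DocumentReference attachment could not be located."""


class UnsupportedFormatError(FedcubeError):
    """A note attachment has a content type the pipeline does not handle (e.g. PDF)."""


class ConfigurationError(FedcubeError):
    """A configuration object (rules, dictionary, spec, secret) is invalid or missing."""


class MergeError(FedcubeError):
    """Aggregate matrices are incompatible (variable lists or study periods diverge)."""


class IncomputableError(FedcubeError):
    """A measure cannot be computed because a needed aggregate cell is suppressed or absent.

    Under aggregate-only federation a missing cell is information, not a zero;
    the analytics layer never imputes it.
    """
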