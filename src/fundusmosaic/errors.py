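"""Exception hierarchy shared by all pipeline stages.

``RegistrationFailure`` and its subclasses are *failure signals*: the
orchestration layer catches them and turns them into a self-reported
failure in the registration report rather than crashing.
"""


class FundusMosaicError(Exception):
    """Base class for all package errors."""


class FormatError(FundusMosaicError):
    """Unreadable or unsupported image file."""


class ParameterError(FundusMosaicError):
    """Invalid configuration or operation parameter."""


class InputError(FundusMosaicError):
    """Structurally invalid input data (mismatched counts, missing field)."""


class RegistrationFailure(FundusMosaicError):
    """A pipeline stage could not produce a usable transform."""


class DegenerateInputError(RegistrationFailure):
    """Input carries too little structure to proceed (e.g. featureless image)."""


class UndefinedValueError(RegistrationFailure):
    """A requested statistic is undefined for the given input (e.g. empty overlap)."""


class GenerationError(FundusMosaicError):
    """Synthetic-scene geometry cannot satisfy the requested constraints."""
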