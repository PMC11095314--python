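"""Exception hierarchy shared across the pipeline."""


class PhyloEMGError(Exception):
    """Base class for all package errors."""


class FormatError(PhyloEMGError):
    """A file does not conform to its expected layout."""


class EmptyInputError(FormatError):
    """A file or table contains no usable rows."""


class ValidationError(PhyloEMGError, ValueError):
    """A value violates a documented precondition or invariant."""


class DegenerateSignalError(ValidationError):
    """A signal has zero range (or a burst zero extent) where spread is required."""
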