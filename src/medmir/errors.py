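"""Exception types shared across the pipeline."""


class MedmirError(ValueError):
    """Base class for all package-specific errors."""


class SizingError(MedmirError):
    """A requested simulation layout cannot fit (too many genes, batches, ...)."""


class AnnotationError(MedmirError):
    """Coordinates fall outside the reference or violate the annotation contract."""


class InputError(MedmirError):
    """Malformed or inconsistent user input."""


class ParseError(MedmirError):
    """A file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class SampleQualityError(MedmirError):
    """A sample fails a quality precondition (e.g. no detectable miRNAs)."""


class DistanceUndefinedError(MedmirError):
    """A pairwise distance cannot be computed (too few shared observations)."""
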