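"""Exception hierarchy for the leaf-grading pipeline.

All package errors derive from :class:`LeafGradeError`.  Validation problems
(bad parameters, malformed configuration) raise :class:`ValidationError`
subclasses; failures while processing data raise :class:`ProcessingError`
subclasses.  The CLI maps the former to exit code 2 and the latter to 3.
"""


class LeafGradeError(Exception):
    """Base class for all errors raised by leafgrade."""


class ValidationError(LeafGradeError):
    """Invalid parameters or configuration supplied by the caller."""


class ParameterError(ValidationError):
    """A numeric parameter is out of its valid range."""


class ConfigurationError(ValidationError):
    """A configuration object or file is malformed or incomplete."""


class SizingError(ValidationError):
    """A canvas is too small for the requested leaf geometry."""


class ProcessingError(LeafGradeError):
    """A pipeline stage failed on otherwise valid input."""


class GenerationError(ProcessingError):
    """The synthetic generator could not satisfy its constraints."""


class DetectionError(ProcessingError):
    """No leaf foreground could be detected in an image."""


class ContourError(ProcessingError):
    """No closed connected contour could be extracted."""


class AmbiguityError(ContourError):
    """Multiple similar-size candidate objects were found."""


class GeometryError(ProcessingError):
    """A polygon operation received degenerate or invalid geometry."""


class TextureError(ProcessingError):
    """A co-occurrence computation had no valid pixel pairs."""


class DataError(ProcessingError):
    """Training or feature data is unusable (non-finite, empty mask, ...)."""


class DegenerateDataError(DataError):
    """Training data does not contain every required class."""


class NumericalError(ProcessingError):
    """A numerically degenerate intermediate value was encountered."""
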