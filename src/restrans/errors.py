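"""Exception hierarchy for the restrans pipeline.

Every stage raises a subclass of :class:`RestransError` so the pipeline
runner can abort with the stage name and the offending entity.
"""


class RestransError(Exception):
    """Base class for all restrans errors."""


class FormatError(RestransError):
    """A file or table violates the expected on-disk format."""


class EmptyResultError(RestransError):
    """A filter or selection removed everything."""


class EmptySelectionError(RestransError):
    """A metadata predicate selected no samples."""


class UndefinedDistanceError(RestransError):
    """A dissimilarity is undefined (e.g. a sample with no observed taxa)."""


class DegenerateDesignError(RestransError):
    """The grouping design cannot support the requested test."""


class InsufficientDataError(RestransError):
    """Too few observations for the statistic to be defined."""


class ParameterError(RestransError):
    """An argument is outside its documented domain."""


class ValidationError(RestransError):
    """Inputs fail cross-validation (ID coverage, design requirements)."""
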