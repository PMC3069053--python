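"""Exception hierarchy shared across the pipeline."""


class MotudivError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(MotudivError):
    """Malformed input file or record (bad characters, duplicate ids, ...)."""


class AlignmentError(MotudivError):
    """Sequences are not a proper alignment (unequal lengths)."""


class ConsistencyError(MotudivError):
    """Cross-record inconsistency (trap in two transects, unknown specimen, ...)."""


class EmptyInputError(MotudivError):
    """An operation received an empty table or matrix."""


class GenerationError(MotudivError):
    """The synthetic-data generator could not satisfy its constraints."""


class ParameterError(MotudivError):
    """Invalid parameter value for a statistical operation."""


class DegenerateInputError(MotudivError):
    """Input too small or rank-deficient for the requested analysis."""


class UndefinedDistanceError(MotudivError):
    """A pairwise distance is undefined (no comparable sites / all-zero units)."""
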