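"""Exception hierarchy shared across the package."""


class PhenodecoupleError(Exception):
    """Base class for all package-specific errors."""


class InvalidConfigError(PhenodecoupleError, ValueError):
    """A configuration object violates its invariants."""


class InvalidParameterError(PhenodecoupleError, ValueError):
    """A model parameter is outside its admissible range."""


class MissingBlankError(PhenodecoupleError, ValueError):
    """A plate has no (or more than one) control-well reading."""


class DegenerateFitError(PhenodecoupleError, RuntimeError):
    """EM collapsed onto a degenerate component after all restarts."""


class AmbiguousComponentsError(PhenodecoupleError, ValueError):
    """No unique positive (largest-mean) component in a mixture fit."""


class DegenerateMatrixError(PhenodecoupleError, ValueError):
    """A distance matrix or feature matrix has no usable variation."""


class NewickParseError(PhenodecoupleError, ValueError):
    """Malformed Newick input."""


class TableParseError(PhenodecoupleError, ValueError):
    """Malformed tabular input (ragged rows, duplicate labels...)."""


class DependencyError(PhenodecoupleError, ValueError):
    """A pipeline stage was requested without its required inputs."""
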