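"""Exception hierarchy.

Every error raised on purpose by this package derives from
:class:`HornmapError`, so callers (and the CLI) can distinguish domain
failures from programming errors.
"""


class HornmapError(Exception):
    """Base class for all hornmap errors."""


class ParseError(HornmapError):
    """A file or descriptor could not be parsed; message names the offending
    token and, for files, the line number."""


class PhasingError(ParseError):
    """An unphased genotype was encountered where phased data is required."""


class RangeError(HornmapError):
    """A window, span or position lies outside the marker map."""


class AlignmentError(HornmapError):
    """Panels that must share a marker map do not."""


class DegenerateInputError(HornmapError):
    """An operation received an empty or otherwise vacuous input."""


class ConfigurationError(HornmapError):
    """A scenario or pipeline configuration violates its own invariants."""


class LineageError(HornmapError):
    """A descendant cannot be placed in the pedigree."""


class ConflictError(HornmapError):
    """Recombinant evidence is contradictory (empty mapping interval).

    Carries the two offending observations as ``left`` and ``right``.
    """

    def __init__(self, message, left=None, right=None):
        super().__init__(message)
        self.left = left
        self.right = right


class CandidatesExhausted(HornmapError):
    """No untested candidate remains inside the current interval; signals the
    end of a dichotomous genotyping loop."""
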