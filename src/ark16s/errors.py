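"""Exception hierarchy for ark16s.

Every error raised deliberately by the package derives from :class:`ArkError`
so callers can catch the whole family with one clause.
"""


class ArkError(Exception):
    """Base class for all ark16s errors."""


class InvalidAlphabetError(ArkError):
    """A k-mer or sequence contains characters outside {A, C, G, T}."""


class DegenerateReadError(ArkError):
    """A read contains no valid k-mer window (too short or all-ambiguous)."""


class EmptyClusterError(ArkError):
    """An operation that needs a nonempty point subset received an empty one."""


class ShapeError(ArkError):
    """Array dimensions do not match between operands."""


class TooFewPointsError(ArkError):
    """Fewer data points than requested clusters."""


class InvalidParametersError(ArkError):
    """Parameter combination violates a precondition (e.g. window <= overlap)."""


class MissingTaxonError(ArkError):
    """A reference sequence ID has no entry in the taxonomy map."""


class EmptyReferenceError(ArkError):
    """Reference construction produced no columns."""


class ZeroEstimateError(ArkError):
    """An estimator produced an all-zero solution that cannot be normalized."""


class AlignmentError(ArkError):
    """Two composition vectors are not over the same taxa in the same order."""


class InvalidDistanceError(ArkError):
    """A distance matrix is not symmetric / has nonzero diagonal."""


class InvalidConfigError(ArkError):
    """A configuration object violates its invariants."""


class ParseError(ArkError):
    """A sequence or profile file is malformed."""


class EmptyInputError(ArkError):
    """An input file contains no records."""
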