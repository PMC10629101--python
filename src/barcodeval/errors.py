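"""Exception hierarchy for barcodeval.

Every error raised intentionally by the package derives from
:class:`BarcodevalError`, so callers can catch one type at pipeline level.
"""


class BarcodevalError(Exception):
    """Base class for all barcodeval errors."""


class InputError(BarcodevalError):
    """Unusable input file (empty, unreadable, malformed)."""


class AlignmentError(BarcodevalError):
    """Sequences violate an alignment invariant (length, alphabet, ...)."""


class MetadataError(BarcodevalError):
    """Sample metadata is missing, duplicated, or inconsistent."""


class ConcatenationError(BarcodevalError):
    """Marker concatenation is impossible (empty intersection, <2 species)."""


class DistanceError(BarcodevalError):
    """Distance computation or group summary is undefined."""


class GapUndefinedError(DistanceError):
    """Barcoding gap cannot be assessed (no intra- or interspecific pairs)."""


class PairingError(BarcodevalError):
    """No shared valid pairs to match between two distance matrices."""


class TestError(BarcodevalError):
    """A statistical test is undefined on the given data."""


class RuleError(BarcodevalError):
    """Diagnostic rule induction precondition violated."""


class IdentificationError(BarcodevalError):
    """Best-match identification precondition violated."""


class TreeError(BarcodevalError):
    """Tree construction precondition violated."""


class SimulationError(BarcodevalError):
    """Contradictory simulation specification."""
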