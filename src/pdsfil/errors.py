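"""Exception hierarchy shared across the toolkit."""


class PdsfilError(Exception):
    """Base class for all toolkit errors."""


class ParameterError(PdsfilError, ValueError):
    """Invalid parameter or specification."""


class ParseError(PdsfilError, ValueError):
    """Malformed structure file."""


class SpaceGroupError(PdsfilError, ValueError):
    """Unsupported or unresolvable space group."""


class UnknownElementError(PdsfilError, KeyError):
    """Element without a van der Waals radius assignment."""


class BuriedSiteError(PdsfilError, RuntimeError):
    """No sterically accepted label position at a site."""


class GridError(PdsfilError, ValueError):
    """Distance grid does not cover the support of the data."""


class DegenerateInputError(PdsfilError, RuntimeError):
    """Inversion produced an all-zero or otherwise degenerate solution."""


class EmptyMixtureError(PdsfilError, RuntimeError):
    """A distance-distribution mixture ended up with no components."""


class StraightFilamentError(PdsfilError, RuntimeError):
    """Helix fit requested on (near-)collinear points."""


class SegmentDeformedError(PdsfilError, RuntimeError):
    """Head-to-tail superposition RMSD exceeded its threshold."""
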