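"""Exception hierarchy for knotswap."""


class KnotswapError(Exception):
    """Base class for all package errors."""


class InvalidGeometryError(KnotswapError, ValueError):
    """Geometric input outside its physical domain (r <= 0, theta outside [0, pi], ...)."""


class EscapedSlabError(KnotswapError):
    """A bead left the slab between the confining walls."""


class InfeasibleConfinementError(KnotswapError):
    """Requested wall separation cannot be met by the chain contour."""


class ConstructionError(KnotswapError):
    """Knotted initial configuration could not be built as requested."""


class RelaxationFailureError(KnotswapError):
    """Relaxation changed the chain topology; result discarded."""


class ClosureError(KnotswapError):
    """Chain closure arc could not avoid the chain."""


class ProjectionError(KnotswapError):
    """No generic projection direction found."""


class IntegrationBlowupError(KnotswapError):
    """A bond exceeded its maximum extension during MD; reduce the time step."""


class BoundaryNotFoundError(KnotswapError):
    """Monomer-removal scan exhausted the chain without a classification change."""


class LocalizationError(KnotswapError):
    """Inconsistent knot boundaries (end before start)."""
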