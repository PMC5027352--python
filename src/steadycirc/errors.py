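"""Exception hierarchy for steadycirc.

All model-construction and solver failures derive from :class:`ModelError`
so callers can catch one base class at the CLI boundary.
"""


class ModelError(Exception):
    """Base class for all steadycirc errors."""


class InvalidModelError(ModelError, ValueError):
    """A model violates a structural or numerical invariant
    (non-positive compliance, zero-resistance parallel branch, ...)."""


class UnsupportedTopologyError(ModelError, ValueError):
    """A vascular circuit is not expressible as a series-parallel tree
    (or a topology description is malformed).  Arbitrary resistor graphs
    are rejected, not approximated."""


class SpecialCaseError(ModelError, ValueError):
    """An operation requiring the balanced heart special case
    (K_R == K_L and equal external pressures) was applied to an
    unbalanced model.  Use the general solver instead."""


class DomainError(ModelError, ValueError):
    """An argument lies outside the mathematical domain of an operation
    (e.g. inverting a cardiac curve at a flow outside (0, K))."""


class NoSolutionError(ModelError, RuntimeError):
    """The steady-state equation has no root in the physiological
    bracket; the message carries the residual values at the bracket
    endpoints for diagnosis."""
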