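"""Exception hierarchy shared across the analysis stages."""


class MicroBCRError(Exception):
    """Base class for all package errors."""


class InvalidGeometryError(MicroBCRError):
    """Reactor geometry violates its invariants (non-positive dimension, ...)."""


class InvalidFluidError(MicroBCRError):
    """Fluid properties violate their invariants (e.g. zero viscosity)."""


class NoTracerDetectedError(MicroBCRError):
    """Initial and final reference grey levels are indistinguishable."""


class HomogeneityNotReachedError(MicroBCRError):
    """The normalized mixing trace never reaches the homogeneity threshold."""


class InsufficientDataError(MicroBCRError):
    """Too few usable samples for a fit."""


class SchemaError(MicroBCRError):
    """A CSV or frame stack does not match the expected schema/metadata."""
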