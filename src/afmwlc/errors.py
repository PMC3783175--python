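"""Exception hierarchy for the afmwlc pipeline."""


class AfmWlcError(Exception):
    """Base class for all afmwlc errors."""


class ParameterError(AfmWlcError, ValueError):
    """A parameter is out of its admissible range."""


class DiscretizationError(ParameterError):
    """Chain discretization too coarse for the Gaussian-increment approximation."""


class SamplingError(AfmWlcError, RuntimeError):
    """A stochastic generator exhausted its retry budget or lacks support."""


class GeometryError(AfmWlcError, ValueError):
    """Geometry does not fit the requested raster / bounds."""


class TraceError(AfmWlcError, RuntimeError):
    """Backbone tracing failed (branched skeleton, too-short molecule, ...)."""


class BranchError(TraceError):
    """Skeleton has more than two endpoints after pruning."""


class ClassificationError(AfmWlcError, RuntimeError):
    """Molecule topology could not be classified unambiguously."""


class FitError(AfmWlcError, RuntimeError):
    """Nonlinear fit did not converge or hit its parameter bounds."""


class ConfigError(AfmWlcError, ValueError):
    """Run configuration failed schema validation."""
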