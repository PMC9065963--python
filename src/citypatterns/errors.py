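"""Exception hierarchy shared across the package."""


class CityPatternsError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(CityPatternsError, ValueError):
    """A model or kernel parameter is invalid."""


class DomainSizeError(CityPatternsError, ValueError):
    """The periodic domain is too small relative to a kernel length scale."""


class GridMismatchError(CityPatternsError, ValueError):
    """Two fields that must share a grid do not."""


class InvariantViolationError(CityPatternsError, ValueError):
    """A field violates a state invariant (p >= 0 or 0 <= s <= 1)."""


class UnsupportedVariantError(CityPatternsError, ValueError):
    """Operation not defined for the requested model variant."""


class NoSteadyStateError(CityPatternsError, RuntimeError):
    """No homogeneous steady state could be bracketed."""


class NoWindowError(CityPatternsError, RuntimeError):
    """No unstable wavenumber window exists at this state."""


class DegenerateInputError(CityPatternsError, ValueError):
    """Input carries no usable signal (e.g. zero variance)."""


class IntegrationError(CityPatternsError, RuntimeError):
    """Time integration failed or violated state invariants."""


class BranchEndError(CityPatternsError, RuntimeError):
    """Newton corrector failed to converge after step refinement."""


class ConfigError(CityPatternsError, ValueError):
    """A run configuration contains unknown or inconsistent entries."""
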