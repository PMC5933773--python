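"""Exception hierarchy used across the package."""


class UnfoldingError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(UnfoldingError, ValueError):
    """Invalid model/kernel configuration (unknown kernel, bad constraint map...)."""


class ParameterError(UnfoldingError, ValueError):
    """Item or density parameters violate their domain (e.g. rho <= 0, non-PD Sigma)."""


class DataError(UnfoldingError, ValueError):
    """Malformed response data (out-of-range codes, ragged rows...)."""


class NumericalError(UnfoldingError, RuntimeError):
    """Numerical failure (likelihood underflow, non-finite Hessian entries...)."""


class ResourceError(UnfoldingError, RuntimeError):
    """A requested computation is too large (e.g. quadrature grid over 1e7 nodes)."""
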