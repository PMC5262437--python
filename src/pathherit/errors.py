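"""Exception hierarchy shared across the package."""


class PathheritError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(PathheritError, ValueError):
    """An argument is outside its documented domain."""


class FormatError(PathheritError, ValueError):
    """An input file violates its format contract."""


class ConfigurationError(PathheritError, ValueError):
    """A run configuration is internally inconsistent."""


class AnalysisError(PathheritError, RuntimeError):
    """An analysis step cannot proceed on the given data."""


class IdentifiabilityError(AnalysisError):
    """Variance components cannot be separated for the supplied matrices."""


class NumericalError(PathheritError, ArithmeticError):
    """A numerical invariant was violated beyond tolerance."""
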