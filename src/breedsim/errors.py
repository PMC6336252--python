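"""Exception types shared across the package."""


class BreedsimError(Exception):
    """Base class for package-specific errors."""


class InvalidConfigurationError(BreedsimError, ValueError):
    """A simulation or model parameter is outside its valid range."""


class DegenerateDataError(BreedsimError, ValueError):
    """Input data carry no usable signal (e.g. all markers monomorphic)."""


class MonomorphicLocusError(BreedsimError, ValueError):
    """A locus required to be polymorphic is fixed; LD is undefined."""


class UndefinedReliabilityError(BreedsimError, ValueError):
    """A correlation-based reliability is undefined (constant vector)."""
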