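"""Exception hierarchy shared across the pipeline stages."""


class MolarageError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(MolarageError, ValueError):
    """An invalid configuration value; the message names the offending field."""


class SizeError(MolarageError, ValueError):
    """Requested contents do not fit the available grid or container."""


class ShapeError(MolarageError, ValueError):
    """Array shapes of an image/mask pair do not agree."""


class DomainError(MolarageError, ValueError):
    """A value outside the mathematical domain of an operation (e.g. ln of a
    non-positive tissue volume)."""


class InsufficientDataError(MolarageError, ValueError):
    """Too few participants remain to carry out the requested computation."""


class DegenerateDesignError(MolarageError, ValueError):
    """A design matrix cannot be built (e.g. a sex-stratified model on
    single-sex data)."""


class SingularDesignError(MolarageError, ValueError):
    """The design matrix is rank deficient."""


class DegenerateFitError(MolarageError, ValueError):
    """A fit with (numerically) zero residual variance; its likelihood is
    unbounded and AIC undefined."""


class SelectionError(MolarageError, ValueError):
    """Every candidate model in a selection grid was degenerate."""


class DegeneratePosteriorError(MolarageError, ValueError):
    """The likelihood vanished (or was non-finite) everywhere on the prior
    support, so no posterior can be normalized."""


class ConsistencyError(MolarageError, ValueError):
    """Cross-table identifiers do not match."""
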