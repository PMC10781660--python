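"""Exception hierarchy for model construction and simulation."""


class PottsError(Exception):
    """Base class for all package-specific errors."""


class UnsupportedDimensionError(PottsError, ValueError):
    """Space has a number of axes other than 2 or 3."""


class InvalidSizeError(PottsError, ValueError):
    """An axis length is too small for the requested boundary condition."""


class EmptyDomainError(PottsError, ValueError):
    """A mask defines no foreground pixels."""


class PlacementConflictError(PottsError, ValueError):
    """Explicitly positioned cells overlap or fall outside the domain."""


class CrowdingError(PottsError, RuntimeError):
    """No room to place a cell (upfront or after bounded retries)."""


class ConfigurationError(PottsError, ValueError):
    """Inconsistent or incomplete model configuration."""


class MissingCellError(PottsError, KeyError):
    """Operation on a cell id absent from the cell table."""


class TooSmallToDivideError(PottsError, ValueError):
    """Division requested for a cell with fewer than 2 nodes."""


class IntegrationFailureError(PottsError, RuntimeError):
    """ODE integration failed (e.g. non-finite derivative), names the cell."""


class LoadError(PottsError, RuntimeError):
    """Saved file is corrupt, truncated, or has an unknown version."""


class ContractViolationError(PottsError, RuntimeError):
    """An internal precondition was violated (e.g. topology query on medium)."""
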