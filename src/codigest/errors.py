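"""Exception hierarchy shared across the package."""


class CodigestError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(CodigestError, ValueError):
    """Raised when an input violates a documented invariant."""


class CompositionError(CodigestError, ValueError):
    """Raised when an elemental composition cannot yield the requested quantity
    (too oxidized for methane, non-combustible, already fully oxidized)."""


class ParseError(CodigestError, ValueError):
    """Raised when an input file cannot be parsed; carries a line number where known."""


class SimulationError(CodigestError, ValueError):
    """Raised when a synthetic-data configuration is infeasible or inconsistent."""
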