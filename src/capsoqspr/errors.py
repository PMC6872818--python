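"""Exception hierarchy shared across the package.

Errors are grouped so the command-line layer can map them to distinct
exit codes: configuration problems, data problems, numerical failures.
"""


class CapsoError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(CapsoError, ValueError):
    """Invalid hyperparameter or configuration value."""


class ContractError(CapsoError, ValueError):
    """Caller violated an interface contract (shape/dimension mismatch)."""


class ChaosDomainError(CapsoError, ValueError):
    """Chaos variable left the unit interval."""


class DataValidationError(CapsoError, ValueError):
    """A descriptor table failed validation."""


class OptimizationError(CapsoError, RuntimeError):
    """Numerical failure during swarm search or gradient refinement."""
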