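"""Exception types raised by the idti model."""


class IdtiError(Exception):
    """Base class for all idti errors."""


class InvalidParameterError(IdtiError, ValueError):
    """A parameter violates its physical or numerical constraints."""


class ModelBreakdownError(IdtiError):
    """A model assumption failed (e.g. fast-water fraction exceeding 1)."""


class DegenerateSchemeError(IdtiError):
    """Gradient scheme cannot support a tensor fit (rank-deficient design)."""


class ConfigurationError(IdtiError):
    """Invalid run or phantom configuration."""
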