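"""Exception hierarchy used across the pipeline."""


class NpmineError(Exception):
    """Base class for all package errors."""


class ValidationError(NpmineError):
    """An input object violates a documented precondition."""


class ConfigurationError(NpmineError):
    """A parameter set or config file is inconsistent."""


class InternalConsistencyError(NpmineError):
    """An internal invariant was violated (indicates a bug upstream)."""
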