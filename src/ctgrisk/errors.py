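"""Exception types shared across the package."""


class CTGError(Exception):
    """Base class for all ctgrisk errors."""


class ValidationError(CTGError, ValueError):
    """A record, trace or table violated its schema or an invariant."""


class ConfigError(CTGError, ValueError):
    """An invalid configuration (non-positive rates, infeasible targets...)."""


class ExtractionError(CTGError, RuntimeError):
    """Feature extraction could not proceed (e.g. all-missing trace)."""


class ParseError(ValidationError):
    """A file did not match the expected CSV dialect."""
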