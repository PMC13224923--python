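"""Exception hierarchy for the ckmstage package."""


class CkmStageError(Exception):
    """Base class for all package errors."""


class CodeValidationError(CkmStageError):
    """A string is not a well-formed ICD-10-CM code."""


class RegistryError(CkmStageError):
    """A registry document is structurally invalid or internally inconsistent."""


class ClaimsFormatError(CkmStageError):
    """A claims or measurements table violates the declared CSV dialect."""


class ConfigurationError(CkmStageError):
    """A staging run was configured inconsistently."""
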