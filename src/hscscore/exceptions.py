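"""Exception hierarchy.

Validation errors signal data that violates an invariant (negative counts,
duplicate identifiers); format errors signal files that cannot be parsed as
the declared format; configuration errors signal inconsistent settings
(e.g. a QC threshold that needs metadata the matrix does not carry).
"""


class HscScoreError(Exception):
    """Base class for all package errors."""


class ValidationError(HscScoreError):
    """Input data violates a documented invariant."""


class FormatError(HscScoreError):
    """A file does not conform to its declared on-disk format."""


class ConfigurationError(HscScoreError):
    """Settings are internally inconsistent or incomplete."""
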