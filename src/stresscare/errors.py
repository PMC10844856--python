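"""Typed exceptions used across the package.

Every malformed input raises one of these — never a bare ``Exception`` and
never a silent partial result.
"""


class StressCareError(Exception):
    """Base class for all package errors."""


class FormatError(StressCareError):
    """A file or manifest does not conform to the expected on-disk format."""


class ValidationError(StressCareError):
    """Input data violates a documented invariant or precondition."""


class ConfigurationError(StressCareError):
    """A configuration value is out of range or inconsistent."""


class ExternalDataError(StressCareError):
    """An optional external dataset is not present locally."""
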