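"""Exception hierarchy shared by all pipeline stages.

Every error a stage can raise on bad input derives from :class:`SaltomicsError`
so the command-line layer can map them to exit code 2 uniformly.
"""


class SaltomicsError(Exception):
    """Base class for all saltomics errors."""


class ParseError(SaltomicsError):
    """A file could not be parsed; the message names the offending line/cell."""


class ValidationError(SaltomicsError):
    """Input violated an invariant (coordinates, schema, thresholds...)."""


class DesignError(ValidationError):
    """A table's column labels do not match the experiment design."""


class ConfigurationError(SaltomicsError):
    """A configuration value is out of range or internally inconsistent."""


class QuantificationError(SaltomicsError):
    """Absolute quantification impossible (e.g. spiked standard absent)."""
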