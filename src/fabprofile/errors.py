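"""Exception hierarchy for the fabprofile pipeline."""


class FabprofileError(Exception):
    """Base class for all package-specific errors."""


class MzmlParseError(FabprofileError):
    """The mzML document is malformed or missing required elements."""


class EmptyRunError(FabprofileError):
    """The mzML document contains no MS1 spectra with retention times."""


class SchemaError(FabprofileError):
    """A tabular file (clone table, similarity matrix) violates its schema."""


class ConfigError(FabprofileError):
    """A pipeline configuration value is missing, unknown or invalid."""
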