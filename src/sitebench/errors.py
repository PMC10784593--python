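"""Exception hierarchy."""


class SitebenchError(Exception):
    """Base class for all package errors."""


class SchemaError(SitebenchError):
    """A file or feature table does not conform to the declared schema."""


class IntegrityError(SitebenchError):
    """Cross-file consistency violated (duplicate or unmatched subjects)."""


class ConfigError(SitebenchError):
    """Invalid configuration or parameter value."""


class FitError(SitebenchError):
    """A model cannot be estimated on the provided data."""
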