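"""Exception types shared across the package."""


class LamselError(Exception):
    """Base class for package-specific errors."""


class ConfigurationError(LamselError):
    """Invalid simulation or pipeline configuration."""


class AlignmentError(LamselError):
    """Laminar alignment failed (no discernible CSD profile)."""


class SchemaError(LamselError):
    """Session container is malformed or incomplete."""


class WindowError(LamselError):
    """Requested analysis window lies outside the recording."""
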