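"""Exception hierarchy.

All package-specific failures derive from :class:`MeprodError` so callers (and
the CLI) can distinguish data/validation problems from programming errors.
"""


class MeprodError(Exception):
    """Base class for all errors raised by this package."""


class DesignError(MeprodError):
    """Invalid plex design: missing/duplicate roles, bad channel metadata."""


class FormatError(MeprodError):
    """Malformed peptide/protein table input."""


class ConfigError(MeprodError):
    """Invalid simulation configuration."""


class NormalizationError(MeprodError):
    """Total-intensity normalization cannot be carried out (e.g. empty channel)."""
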