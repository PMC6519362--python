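"""Exception hierarchy for msiscope.

All package-specific failures derive from :class:`MsiscopeError` so callers
(and the CLI) can distinguish pipeline faults from programming errors.
"""


class MsiscopeError(Exception):
    """Base class for all msiscope failures."""


class ParseError(MsiscopeError):
    """A file could not be parsed; the message names the file and line."""


class ValidationError(MsiscopeError):
    """Parsed content violates a panel or table invariant."""


class InputReadError(MsiscopeError):
    """A sequencing read contains characters other than A/C/G/T/N."""


class DegenerateVarianceError(MsiscopeError):
    """All control frequencies at a marker are identical; Beta fit impossible."""


class InvalidMomentsError(MsiscopeError):
    """Sample variance too large for a Beta distribution (moments factor <= 0)."""


class UnscorableSampleError(MsiscopeError):
    """No marker of a sample passed QC and is covered by the control model."""


class PanelMismatchError(MsiscopeError):
    """A control model and a counts table derive from different panels."""


class ConfigError(MsiscopeError):
    """Invalid simulation or pipeline configuration."""
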