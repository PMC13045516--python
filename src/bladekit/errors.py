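"""Exception hierarchy.

``BladeUserError`` covers everything caused by bad inputs or configuration
(CLI exit code 1); anything else escaping the library is an internal error
(CLI exit code 2).
"""


class BladeError(Exception):
    """Base class for all package errors."""


class BladeUserError(BladeError):
    """Input, configuration or precondition failure attributable to the caller."""


class FormatError(BladeUserError):
    """File exists but is not in the expected format."""


class AlignmentError(BladeUserError):
    """Image/mask/AIF grids do not align."""


class EmptyROIError(BladeUserError):
    """Requested label selects no voxels (or none usable)."""


class InsufficientDataError(BladeUserError):
    """Too few samples/b-values/frames for the requested fit."""


class DegenerateInputError(BladeUserError):
    """Constant or otherwise degenerate input where variation is required."""


class ConversionError(BladeUserError):
    """Signal-to-concentration conversion cannot proceed (e.g. non-positive baseline)."""


class ConfigError(BladeUserError):
    """Invalid configuration key or value."""
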