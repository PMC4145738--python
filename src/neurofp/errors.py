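"""Exception hierarchy shared across the package."""


class NeurofpError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(NeurofpError, ValueError):
    """Input violates a documented precondition or invariant."""


class FormatError(NeurofpError, ValueError):
    """A file's contents do not match the expected on-disk format."""


class DegenerateRoiError(ValidationError):
    """An ROI operation produced (or received) an unusable region,
    e.g. an empty rater intersection or a zero-signal mirror reference."""
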