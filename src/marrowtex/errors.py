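"""Exception hierarchy shared across the package."""


class MarrowtexError(Exception):
    """Base class for all package errors."""


class FormatError(MarrowtexError, ValueError):
    """Malformed or mutually inconsistent input files (e.g. shape mismatch)."""


class DegenerateROIError(MarrowtexError, ValueError):
    """ROI too small or too uniform for the requested computation."""


class ValidationError(MarrowtexError, ValueError):
    """Invalid labels, duplicate entries, or broken table contracts."""


class ParameterError(MarrowtexError, ValueError):
    """Out-of-range configuration parameter."""


class SampleSizeError(MarrowtexError, ValueError):
    """Statistical routine called with too few observations."""
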