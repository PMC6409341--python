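"""Exception hierarchy for the optical quantal analysis pipeline."""


class OQAError(Exception):
    """Base class for all package errors."""


class ConfigurationError(OQAError):
    """Invalid parameters, ROI geometry, or config file contents."""


class DegenerateNormalizationError(OQAError):
    """F_baseline <= F_background: the dF/F denominator is non-positive.

    The trial is unanalyzable (e.g. the spine ROI missed the structure or
    the background ROI contains fluorescent structure) and must be flagged,
    never silently dropped.
    """


class DegenerateNoiseError(OQAError):
    """Baseline noise estimate is zero; the threshold test is undefined."""


class WindowError(OQAError):
    """An analysis window falls outside the scanned time range."""


class ProtocolError(OQAError):
    """The stimulation protocol does not support the requested analysis."""


class EstimationError(OQAError):
    """No analyzable trials remain to estimate from."""
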