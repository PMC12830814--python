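"""Exception hierarchy."""


class MetaPRSError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(MetaPRSError, ValueError):
    """A configuration object violates its invariants."""


class EmptyPanelError(MetaPRSError):
    """QC removed every variant (or sample) from the panel."""


class ParseError(MetaPRSError, ValueError):
    """A scoring/covariate file could not be parsed."""


class FitError(MetaPRSError, RuntimeError):
    """A model fit failed (separation, rank deficiency, non-convergence)."""


class ScoreError(MetaPRSError, ValueError):
    """Score computation or combination is undefined for the given inputs."""
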