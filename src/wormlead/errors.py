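"""Exception hierarchy.

Every error raised by the package derives from :class:`WormleadError`, so
callers can catch one type at a pipeline boundary while tests can assert on
the specific failure mode.
"""


class WormleadError(Exception):
    """Base class for all package errors."""


class StructureError(WormleadError):
    """A structure string could not be parsed or violates a structural invariant."""


class ValidationError(WormleadError):
    """Tabular or configuration input violates a contract (missing column, bad value)."""


class ConfigError(WormleadError):
    """Unknown model version, unordered desirability knots, unsupported option."""


class ComputationError(WormleadError):
    """A descriptor or scoring engine failed for a specific compound."""


class AggregationError(WormleadError):
    """An empty group was passed to a summary operation."""


class ComparisonError(WormleadError):
    """Two objects cannot be compared (mismatched fingerprints, single group)."""


class FitError(WormleadError):
    """A regression is degenerate or failed to converge; carries diagnostics text."""


class EstimationError(WormleadError):
    """A survival estimate cannot be formed (e.g. no deaths observed)."""


class SpectrumError(WormleadError):
    """Spectrum axis problems: window out of range, missing reference peak, misaligned axes."""
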