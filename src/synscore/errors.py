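"""Exception hierarchy for synscore.

All package-specific failures derive from :class:`SynscoreError` so callers
can catch one base class; batch drivers additionally distinguish data-shaped
problems (bad input files, degenerate blocks) from batch-level failure.
"""


class SynscoreError(Exception):
    """Base class for all synscore errors."""


class DataError(SynscoreError):
    """Input data is malformed or contains non-finite values."""


class FormatError(DataError):
    """A required column or field is missing from an input table."""


class ConflictError(DataError):
    """Duplicate measurements for the same (doses, replicate) coordinate."""


class MissingDataError(DataError):
    """A combination cell of the dose grid has no measurable response."""


class NormalizationError(DataError):
    """Count normalization impossible (e.g. no negative-control wells)."""


class DegenerateControlError(NormalizationError):
    """Positive and negative control means coincide."""


class InsufficientDataError(DataError):
    """Too few doses/points for the requested fit or reconstruction."""


class DegenerateCurveError(SynscoreError):
    """Fitted dose-response curves do not support the requested operation
    (e.g. non-overlapping response ranges for Loewe, lower asymptote ~100%
    for the concentration weight)."""


class ConsistencyError(SynscoreError):
    """A report or result refers to a block it was not generated from."""


class BatchError(SynscoreError):
    """No block in a multi-sample batch could be scored.

    Carries per-block diagnostics in :attr:`diagnostics`.
    """

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class ResponseBelowRange(SynscoreError):
    """Requested response lies at/below the curve's lower asymptote.

    The equivalent dose is 0; the Loewe solver treats the dose ratio as
    unbounded.
    """


class ResponseAboveRange(SynscoreError):
    """Requested response lies at/above the curve's upper asymptote: no
    finite dose achieves it (saturation signal for the Loewe solver)."""
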