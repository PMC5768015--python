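"""Exception hierarchy shared across the toolkit.

All errors derive from :class:`LiverKBPError` so callers can catch the
package's failures with a single handler; the concrete subclasses mirror
the distinct failure modes of plan evaluation and model fitting.
"""


class LiverKBPError(Exception):
    """Base class for all liverkbp errors."""


class EmptyStructureError(LiverKBPError):
    """A structure mask contains no voxels where at least one is required."""


class CongruenceError(LiverKBPError):
    """Arrays that must share a grid (dose vs. mask, mask vs. mask) do not."""


class DomainError(LiverKBPError, ValueError):
    """A scalar argument lies outside its physical or mathematical domain."""


class DegeneratePlanError(LiverKBPError):
    """A plan-quality index is undefined for this dose distribution."""


class FitError(LiverKBPError):
    """A regression cannot be fitted (too few points, degenerate predictor)."""


class DegenerateTestError(LiverKBPError):
    """A statistical test is undefined (e.g. zero variance of differences)."""


class SchemaError(LiverKBPError):
    """A file or table violates the expected schema; message names the gap."""


class SpecError(LiverKBPError):
    """A generator or run specification is internally inconsistent."""
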