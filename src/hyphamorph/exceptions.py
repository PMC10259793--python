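"""Exception hierarchy for hyphamorph.

Every user-facing failure mode raises a subclass of :class:`HyphamorphError`
so callers (and the CLI) can catch pipeline errors without masking bugs.
"""


class HyphamorphError(Exception):
    """Base class for all hyphamorph errors."""


class InvalidTraceError(HyphamorphError):
    """A polyline trace violates its invariants (too few points, zero-length segment)."""


class InvalidGeometryError(HyphamorphError):
    """Degenerate geometry: coincident points, body axis below resolution, ..."""


class IneligibleCellError(HyphamorphError):
    """A cell fails the inclusion rule for the requested measurement."""


class UnmeasurableTraceError(HyphamorphError):
    """A hypha too short to be measured at the configured simplification tolerance."""


class MissingLabelError(HyphamorphError):
    """Requested label absent from a label mask."""


class InsufficientSampleError(HyphamorphError):
    """Sample too small for the requested statistical test."""


class DegenerateSampleError(HyphamorphError):
    """Sample with zero variance where a spread is required."""


class EmptyGroupError(HyphamorphError):
    """No cells match the requested stage/channel selection."""


class ConfigurationError(HyphamorphError):
    """Invalid configuration (unordered thresholds, bad parameter ranges)."""
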