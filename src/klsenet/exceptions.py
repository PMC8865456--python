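"""Exception hierarchy for the KLSE pipeline.

All pipeline errors derive from :class:`KlseError` so callers can catch a
single base class; the subclasses distinguish the failure modes the
individual stages document.
"""


class KlseError(Exception):
    """Base class for all klsenet errors."""


class CapacityError(KlseError, ValueError):
    """A phantom volume is too small to hold the requested parcels."""


class InputError(KlseError, ValueError):
    """Invalid or inconsistent input data (shape mismatch, bad labels, ...)."""


class FormatError(InputError):
    """A file on disk does not have the expected format."""


class GridMismatchError(InputError):
    """Two density estimates do not share the identical standardized grid."""


class DegenerateSampleError(KlseError, ValueError):
    """A parcel sample is degenerate (constant) so no bandwidth exists."""


class CoverageError(KlseError, ValueError):
    """No sample values fall inside the standardized grid range."""


class UndefinedMetricError(KlseError, ValueError):
    """A graph metric is undefined for the given node set (too few nodes)."""
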