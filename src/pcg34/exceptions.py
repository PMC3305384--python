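"""Exception hierarchy for the pcg34 pipeline."""


class PCGError(Exception):
    """Base class for all pcg34 errors."""


class InputError(PCGError):
    """Unreadable, empty or structurally invalid input data."""


class ParameterError(PCGError):
    """A parameter violates its contract (e.g. cutoff above Nyquist)."""


class DegenerateInputError(PCGError):
    """Input is valid but degenerate for the requested operation (e.g. all zeros)."""


class SegmentationError(PCGError):
    """Cycle segmentation failed (no peaks above threshold, too few peaks, ...)."""


class ClusteringError(PCGError):
    """Too few distinct points to form the three frequency-magnitude groups."""
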