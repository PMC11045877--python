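"""Exception hierarchy for the BiAD quantification pipeline."""


class BiadError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(BiadError):
    """A configuration contract was violated (channel maps, thresholds, simulation geometry)."""


class SegmentationError(BiadError):
    """Nucleus or spot segmentation failed for a cell (e.g. no pixel above threshold)."""


class ExclusionError(BiadError):
    """A cell must be excluded from an analysis; carries a machine-readable reason code."""

    def __init__(self, reason: str, message: str | None = None):
        self.reason = reason
        super().__init__(message or reason)


class DegenerateDataError(BiadError):
    """Statistical input is degenerate (e.g. two identical constant groups)."""
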