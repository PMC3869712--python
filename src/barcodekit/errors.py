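"""Exception hierarchy shared across the package."""


class BarcodekitError(Exception):
    """Base class for all package errors."""


class AlignmentError(BarcodekitError):
    """Sequences violate alignment invariants (unequal lengths, empty library)."""


class MetadataError(BarcodekitError):
    """Metadata table is inconsistent with the sequence library."""


class DuplicateIdError(BarcodekitError):
    """The same seq_id occurs more than once."""


class DistanceError(BarcodekitError):
    """A pairwise distance could not be computed."""

    def __init__(self, message, pair=None):
        super().__init__(message)
        self.pair = pair


class UndefinedDistanceError(DistanceError):
    """No comparable sites between two sequences."""


class SaturationError(DistanceError):
    """Log argument non-positive: the K2P distance is undefined (saturation)."""


class LabelingError(BarcodekitError):
    """A sequence id is missing a required group label."""


class AnalysisError(BarcodekitError):
    """An analysis precondition failed (e.g. an empty distance category)."""
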