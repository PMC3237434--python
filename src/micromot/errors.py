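"""Exception hierarchy shared across the quantification modules."""


class MicromotError(Exception):
    """Base class for all package errors."""


class GeometryError(MicromotError, ValueError):
    """Invalid island geometry or mismatched pixel grids."""


class ClassificationError(MicromotError, ValueError):
    """A point could not be assigned to a boundary region."""


class SegmentationError(MicromotError, ValueError):
    """Thresholding failed (e.g. constant image)."""


class TrackError(MicromotError, ValueError):
    """Invalid cell track (too short, non-increasing times)."""


class IntegrityError(MicromotError, ValueError):
    """Inconsistent tabular input (e.g. duplicate cell/timepoint rows)."""


class ConfigError(MicromotError, ValueError):
    """Invalid or incomplete run configuration."""


class DensityError(MicromotError, ValueError):
    """Synthetic object density exceeds the packing limit."""


class UndefinedStatisticError(MicromotError, ValueError):
    """A requested summary statistic is undefined (e.g. percentage of zero cells)."""
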