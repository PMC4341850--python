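"""Exception hierarchy for the airway-topo pipeline."""


class AirwayTopoError(Exception):
    """Base class for all package errors."""


class FormatError(AirwayTopoError):
    """Unsupported or malformed file format."""


class EmptyVolumeError(AirwayTopoError):
    """A volume with no foreground voxels where foreground is required."""


class EmptySkeletonError(AirwayTopoError):
    """The tri-axial skeleton intersection is empty; the segmentation is unusable."""


class ValidationError(AirwayTopoError):
    """A parameter or input value violates its contract."""


class ConsistencyError(AirwayTopoError):
    """An internal invariant was violated (e.g. a cycle in a predecessor chain)."""
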