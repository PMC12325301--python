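"""Exception hierarchy for cpseg."""


class CpsegError(Exception):
    """Base class for all cpseg errors."""


class VolumeLoadError(CpsegError):
    """A NIfTI file could not be read or failed validation."""


class GridMismatchError(CpsegError):
    """Two volumes do not share the same voxel grid."""


class DegenerateRegionError(CpsegError):
    """The prior region is empty or contains no usable intensities."""


class PipelineError(CpsegError):
    """The segmentation pipeline cannot proceed (e.g. both hemispheres empty)."""
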