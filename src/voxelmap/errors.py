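"""Exception hierarchy for the voxelmap pipeline.

Every stage raises a subclass of :class:`VoxelMapError` so callers (and the
CLI) can distinguish pipeline failures from programming errors.
"""


class VoxelMapError(Exception):
    """Base class for all pipeline errors."""


class InputError(VoxelMapError):
    """A required input is missing, unreadable, or semantically invalid."""


class FormatError(VoxelMapError):
    """A file parsed, but its contents violate the format contract."""


class ParameterError(VoxelMapError):
    """A configuration value is out of its documented range."""
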