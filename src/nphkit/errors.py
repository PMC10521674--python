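"""Exception hierarchy.

Every user-facing failure mode raises a distinct, named error so callers
(and the CLI) can report which contract was violated.
"""


class NPHKitError(Exception):
    """Base class for all package errors."""


class VolumeFormatError(NPHKitError):
    """A volume file exists but is not a readable 3-D NIfTI-1 image."""


class DimensionalityError(VolumeFormatError):
    """The image on disk is not three-dimensional."""


class CorruptHeaderError(VolumeFormatError):
    """The NIfTI header could not be parsed."""


class StreamlineFormatError(NPHKitError):
    """Unknown extension, truncated file, or invalid polyline."""


class MatrixFormatError(NPHKitError):
    """A FLIRT-style 4x4 text matrix is malformed."""


class InvariantError(NPHKitError, ValueError):
    """A domain-type invariant was violated (bad spacing, <2-point polyline ...)."""


class SpaceMismatchError(NPHKitError):
    """Two objects tagged with incompatible coordinate spaces were combined."""


class SingularTransformError(NPHKitError):
    """An affine transform is not invertible."""


class ConfigError(NPHKitError):
    """A pipeline configuration problem detected before any compute."""
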