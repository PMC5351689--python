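"""Exception hierarchy for the sstrtex pipeline."""


class SstrtexError(Exception):
    """Base class for all package errors."""


class VolumeError(SstrtexError):
    """Unreadable or ill-formed image volume."""


class AlignmentError(SstrtexError):
    """Mask and volume grids do not match."""


class SuvConversionError(SstrtexError):
    """SUV conversion refused (missing physics or already converted)."""


class CohortSchemaError(SstrtexError):
    """Cohort table violates the documented schema."""


class PhantomError(SstrtexError):
    """Phantom specification cannot be realized on the voxel grid."""


class DegenerateTextureError(SstrtexError):
    """No valid voxel pair / empty mask: texture matrices undefined."""


class FeatureError(SstrtexError):
    """Feature computation precondition violated."""


class ConvergenceError(SstrtexError):
    """Iterative fit failed to converge (e.g. monotone Cox likelihood)."""


class StratificationError(SstrtexError):
    """ROC/KM precondition violated (single class, empty group, ...)."""
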