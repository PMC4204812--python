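"""Exception types shared across the package."""


class MotionQCError(ValueError):
    """Base class for all motionqc-specific errors."""


class InvalidParameterError(MotionQCError):
    """A realignment-parameter row or series is malformed (non-finite, wrong shape)."""


class GeometryError(MotionQCError):
    """An image-geometry precondition failed (singular affine, mask too small, ...)."""


class EmptyMaskError(MotionQCError):
    """An operation that needs a non-empty binary mask received an empty one."""


class DegenerateDesignError(MotionQCError):
    """A regression design has no usable columns (rank 0 after centering)."""
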