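"""Exception hierarchy for the runfatigue pipeline."""


class RunFatigueError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(RunFatigueError):
    """A domain object violates one of its invariants.

    The message always names the offending field.
    """


class NoRunDetected(RunFatigueError):
    """No sustained running bout could be located in the pelvis velocity."""


class SegmentationError(RunFatigueError):
    """Stride-level segmentation failed (e.g. too few velocity minima)."""
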