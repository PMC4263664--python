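"""Exception hierarchy.

``SegmentationError`` marks recoverable per-slice failures that the pipeline
converts into a failed :class:`~lvseg.pipeline.SliceResult`; plain
``ValueError`` is reserved for malformed inputs / programming errors.
"""


class LvsegError(Exception):
    """Base class for package errors."""


class SegmentationError(LvsegError):
    """A segmentation stage failed on a slice (recoverable at study level)."""

    def __init__(self, message: str, stage: str | None = None):
        super().__init__(message)
        self.stage = stage


class StudyReadError(LvsegError):
    """A study directory could not be read into a :class:`Study`."""
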