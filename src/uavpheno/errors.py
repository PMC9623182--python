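"""Exception and warning types shared across the package."""


class UavPhenoError(Exception):
    """Base class for package errors."""


class FormatError(UavPhenoError, ValueError):
    """A file could not be read or written in the expected format."""


class ValidationError(UavPhenoError, ValueError):
    """An input violates a documented invariant or precondition."""


class DegenerateInputError(UavPhenoError, ValueError):
    """An operation received input on which it is mathematically undefined
    (e.g. a constant sample offered to a histogram-splitting threshold)."""


class PackingError(UavPhenoError, RuntimeError):
    """The scene renderer could not reach the requested vegetation fraction."""


class PipelineConfigError(UavPhenoError, ValueError):
    """A pipeline configuration is incomplete or contains unknown keys."""


class StageFailure(UavPhenoError, RuntimeError):
    """A pipeline stage failed; carries the stage name and offending item."""

    def __init__(self, stage: str, detail: str):
        self.stage = stage
        self.detail = detail
        super().__init__(f"stage {stage!r} failed: {detail}")


class EmptyRegionWarning(UserWarning):
    """A plot polygon intersected no pixel centers."""


class DegenerateSceneWarning(UserWarning):
    """Segmentation ran on a scene without a two-class structure."""


class EmptyMaskWarning(UserWarning):
    """A vegetation mask was empty where one was expected."""
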