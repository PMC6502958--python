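"""Exception hierarchy shared across the pipeline stages."""


class PupilError(Exception):
    """Base class for all pupilrqa errors."""


class FormatError(PupilError):
    """Input file does not match the expected delimited-text layout."""


class EmptyInputError(PupilError):
    """An input signal or table is empty."""


class DegenerateInputError(PupilError):
    """The input exists but carries no usable information (e.g. all blinks)."""


class DomainError(PupilError):
    """A parameter is outside its mathematical domain."""


class EmptyBandError(PupilError):
    """No intrinsic mode function fell inside a required frequency band."""


class UndefinedEntropyError(PupilError):
    """Sample entropy is undefined because no template pairs matched."""


class PipelineStageError(PupilError):
    """Wraps an error raised inside a named pipeline stage."""

    def __init__(self, stage: str, original: Exception):
        self.stage = stage
        self.original = original
        super().__init__(f"stage '{stage}': {original}")
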