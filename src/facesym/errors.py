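"""Exception hierarchy for facesym."""


class FaceSymError(Exception):
    """Base class for all facesym errors."""


class FormatError(FaceSymError, ValueError):
    """An input file does not conform to the expected dialect."""


class EmptySequenceError(FaceSymError, ValueError):
    """A frame sequence contains no usable frames."""


class DegenerateGeometryError(FaceSymError, ValueError):
    """Landmark geometry admits no well-defined normalization."""


class DegenerateInputError(FaceSymError, ValueError):
    """An input (e.g. a depth image) carries too little signal to process."""


class PipelineStageError(FaceSymError, RuntimeError):
    """A stage of the asymmetry pipeline failed; carries the stage name."""

    def __init__(self, stage: str, original: Exception):
        self.stage = stage
        self.original = original
        super().__init__(f"pipeline stage '{stage}' failed: {original}")
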