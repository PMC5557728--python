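"""Exception hierarchy for satlib.

ParameterError signals a caller contract violation (bad argument values),
DataError signals malformed or degenerate input data, and PipelineError wraps
a failure inside a named pipeline stage so orchestration errors always carry
the stage that produced them.
"""


class SatlibError(Exception):
    """Base class for all satlib errors."""


class ParameterError(SatlibError, ValueError):
    """An argument violates an operation's preconditions."""


class DataError(SatlibError):
    """Input data are malformed or degenerate (e.g. empty FASTQ, all-gap alignment)."""


class PipelineError(SatlibError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
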