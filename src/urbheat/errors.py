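"""Exception hierarchy shared across the pipeline."""


class UrbheatError(Exception):
    """Base class for all errors raised by urbheat."""


class ConfigError(UrbheatError):
    """Invalid configuration (unknown scenario/model, bad proportions, ...)."""


class InputError(UrbheatError):
    """Inputs violate an operation's preconditions (grid mismatch, window not covered)."""


class OutOfDomainError(InputError):
    """A coordinate falls outside the grid's latitude span."""


class DataError(UrbheatError):
    """Data inconsistent with its own metadata (orphan records, missing cells)."""


class StageError(UrbheatError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[stage {stage}] {message}")
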