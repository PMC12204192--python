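"""Exception hierarchy shared by all seqspace modules."""


class SeqspaceError(Exception):
    """Base class for all seqspace errors."""


class DuplicateIdError(SeqspaceError):
    """A sequence or (id, level) key appeared more than once."""


class EmptyInputError(SeqspaceError):
    """An operation received an empty file, store or matrix."""


class FormatError(SeqspaceError):
    """A file did not conform to its expected text format.

    Carries the 1-based line number when one is known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class DimensionError(SeqspaceError):
    """A dimensionality constraint was violated (e.g. k > n)."""


class UniverseError(SeqspaceError):
    """Two partitions do not share the same id universe."""


class RefinementError(SeqspaceError):
    """A supposedly finer partition has a cluster spanning two coarse clusters."""


class CoverageError(SeqspaceError):
    """An id required by an operation has no covering entry (vector, representative...)."""


class ParameterError(SeqspaceError):
    """Parameters are internally inconsistent (e.g. inseparable score bands)."""


class MemoryBudgetError(SeqspaceError):
    """A pairwise computation would exceed the configured memory budget."""


class ToolNotFound(SeqspaceError):
    """A required external executable is not on PATH."""


class ExternalToolError(SeqspaceError):
    """An external tool exited non-zero; carries its captured stderr."""

    def __init__(self, message: str, stderr: str = ""):
        self.stderr = stderr
        super().__init__(message if not stderr else f"{message}\n{stderr}")
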