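"""Exception hierarchy shared by all pipeline stages."""


class CrossmirError(Exception):
    """Base class for all package errors."""


class ValidationError(CrossmirError, ValueError):
    """A value violates a documented precondition or invariant."""


class FormatError(CrossmirError, ValueError):
    """A file does not conform to its table contract.

    ``line`` is 1-based and refers to the physical line (or data row)
    that triggered the error, when known.
    """

    def __init__(self, message: str, *, path: str | None = None,
                 line: int | None = None, column: str | None = None):
        self.path = path
        self.line = line
        self.column = column
        parts = [message]
        if path is not None:
            parts.append(f"file={path}")
        if line is not None:
            parts.append(f"line={line}")
        if column is not None:
            parts.append(f"column={column}")
        super().__init__(" | ".join(parts))


class ContractError(CrossmirError, ValueError):
    """An inter-stage contract was violated (e.g. unfiltered records)."""
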