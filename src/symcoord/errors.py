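"""Exception hierarchy.

``ValidationError`` marks bad user input (CLI exit code 2); everything else
derives from :class:`SymcoordError` (CLI exit code 1).
"""


class SymcoordError(Exception):
    """Base class for all symcoord errors."""


class ValidationError(SymcoordError, ValueError):
    """Invalid user input: unknown group, malformed file, bad options."""


class ParseError(ValidationError):
    """Structure file could not be parsed; carries a line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class AssignmentError(SymcoordError):
    """Atom assignment failed (element mismatch, non-isomorphic graphs...)."""


class AlignmentError(SymcoordError):
    """Rigid alignment failed; may carry a best-effort transform."""

    def __init__(self, message: str, best_effort=None, diagnostics=None):
        super().__init__(message)
        self.best_effort = best_effort
        self.diagnostics = diagnostics or {}


class ConvergenceError(SymcoordError):
    """Iterative symmetrization did not converge; carries the final shift."""

    def __init__(self, message: str, final_shift: float | None = None):
        super().__init__(message)
        self.final_shift = final_shift


class SchemaError(ValidationError):
    """JSON document violates a schema; carries the JSON path of the offense."""

    def __init__(self, message: str, path: str = "$"):
        self.path = path
        super().__init__(f"{path}: {message}")
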