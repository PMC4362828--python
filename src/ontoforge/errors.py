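"""Exception hierarchy shared across ontoforge modules."""

from __future__ import annotations


class OntoforgeError(Exception):
    """Base class for all errors raised by ontoforge."""


class SettingsError(OntoforgeError):
    """Malformed or incomplete axiom-settings file."""

    def __init__(self, message: str, lineno: int | None = None):
        self.lineno = lineno
        if lineno is not None:
            message = f"line {lineno}: {message}"
        super().__init__(message)


class ConfigurationError(OntoforgeError):
    """Invalid run configuration (e.g. a relative URI start portion)."""


class TableFormatError(OntoforgeError):
    """Input data table could not be read in the declared format."""


class ManchesterSyntaxError(OntoforgeError):
    """Syntax error in a Manchester class expression; carries a character position."""

    def __init__(self, message: str, pos: int):
        self.pos = pos
        super().__init__(f"{message} (at position {pos})")


class LabelResolutionError(OntoforgeError):
    """One or more quoted labels could not be resolved to URIs.

    ``labels`` lists *all* unknown labels, not just the first encountered.
    """

    def __init__(self, labels: list[str]):
        self.labels = sorted(set(labels))
        quoted = ", ".join(f"'{x}'" for x in self.labels)
        super().__init__(f"unresolvable label(s): {quoted}")


class AllocationError(OntoforgeError):
    """ID capacity exhausted under the active ID policy."""


class RowError(OntoforgeError):
    """A pattern failed for a specific data row."""

    def __init__(self, row: int, pattern: str, detail: str):
        self.row = row
        self.pattern = pattern
        self.detail = detail
        super().__init__(f"row {row}: pattern {pattern!r}: {detail}")


class ValidationFailedError(OntoforgeError):
    """Raised by the engine when validate_settings reports issues."""

    def __init__(self, issues):
        self.issues = list(issues)
        super().__init__(
            "validation failed: " + "; ".join(i.message for i in self.issues)
        )


class SerializationError(OntoforgeError):
    """Output document could not be serialized (unresolved term references)."""
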