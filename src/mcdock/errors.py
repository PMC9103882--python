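"""Exception hierarchy for mcdock.

Every error raised by the library derives from :class:`McdockError` so callers
(and the CLI) can separate input problems from runtime failures.
"""


class McdockError(Exception):
    """Base class for all mcdock errors."""


class InputError(McdockError, ValueError):
    """Malformed or inconsistent user input (files, config, CLI flags)."""


class PDBQTParseError(InputError):
    """A PDBQT record could not be parsed; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class StructureError(InputError):
    """Inconsistent torsion-tree structure (unbalanced or dangling BRANCH)."""


class ConfigError(InputError):
    """Invalid or incomplete docking config."""


class EmptyInputError(InputError):
    """An input that must contain at least one record contains none."""


class DimensionError(McdockError, ValueError):
    """Array shapes or degrees of freedom do not match."""


class TypingError(McdockError, KeyError):
    """Unknown AutoDock atom type."""


class ParameterError(McdockError, ValueError):
    """Infeasible or out-of-range parameter values."""


class ResourceError(McdockError):
    """A computation would exceed a configured resource guard."""
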