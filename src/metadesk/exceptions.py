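"""Exception hierarchy.

All package-specific failures derive from ``MetadeskError`` so callers (and
the CLI) can distinguish domain errors from programming errors.
"""


class MetadeskError(Exception):
    """Base class for all package errors."""


class SelectionError(MetadeskError, ValueError):
    """Malformed atom-selection expression; message names the offending token."""


class CongruenceError(MetadeskError, ValueError):
    """Two objects that must share an atom table do not."""


class GeometryError(MetadeskError, ValueError):
    """Degenerate geometry (collinear selection, coincident centers, ...)."""


class DivergenceError(MetadeskError, RuntimeError):
    """Non-finite energy encountered during integration; carries the step index."""

    def __init__(self, step: int, message: str | None = None):
        self.step = step
        super().__init__(message or f"non-finite energy at step {step}")


class ConfigError(MetadeskError, ValueError):
    """Invalid run configuration (unknown keys, inconsistent parameters)."""


class FormatError(MetadeskError, ValueError):
    """Unparseable or unsupported file content; message carries the line number."""
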