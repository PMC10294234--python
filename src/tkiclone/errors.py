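"""Exception hierarchy shared across the pipeline.

CLI exit-code convention: input/format/configuration problems exit 2,
numerical failures (non-convergence, undefined fits) exit 3.
"""


class TkicloneError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(TkicloneError):
    """Invalid simulation or run configuration."""


class InputError(TkicloneError):
    """Missing or inconsistent user input (files, samples, labels)."""


class FormatError(InputError):
    """A file is syntactically or semantically malformed."""


class ConvergenceError(TkicloneError):
    """An iterative solver failed to reach its tolerance."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class UndefinedFitError(TkicloneError):
    """A fit was requested on degenerate input (e.g. an empty spectrum)."""


class EmptySeedError(TkicloneError):
    """No mutated gene of a subline is present in the interaction graph."""
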