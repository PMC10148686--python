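"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: :class:`InputError` (and subclasses) → 2,
:class:`ModelError` → 3.
"""


class EhmmalignError(Exception):
    """Base class for all package errors."""


class InputError(EhmmalignError):
    """Malformed or inconsistent user input (bad FASTA, unknown ids, ...)."""


class AlignmentShapeError(InputError):
    """Rows of an alignment do not all have the same length."""


class ConfigurationError(InputError):
    """Invalid configuration (unknown ensemble mode, empty backbone, ...)."""


class DecompositionError(EhmmalignError):
    """Tree decomposition cannot proceed (e.g. single-leaf tree)."""


class ModelError(EhmmalignError):
    """Degenerate or internally inconsistent HMM (zero match columns, ...)."""
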