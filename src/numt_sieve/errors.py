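"""Exception hierarchy shared across the toolkit.

Exit-code mapping used by the CLI: usage errors exit 2 (click's default),
:class:`DataError` subclasses exit 3, :class:`InsufficientDataError` and
other degenerate-statistics conditions exit 4.
"""


class NumtSieveError(Exception):
    """Base class for all package-specific errors."""


class ParseError(NumtSieveError, ValueError):
    """Malformed input file (FASTA/Stockholm/Newick/TSV)."""


class DataError(NumtSieveError, ValueError):
    """Structurally valid input that violates a data contract (e.g. an
    unlabeled record id, a non-symmetric distance matrix)."""


class UndefinedValueError(NumtSieveError, ValueError):
    """A statistic is undefined for this input (zero denominator,
    saturated distance, all-ambiguous sequence)."""


class InsufficientDataError(NumtSieveError, ValueError):
    """Too few observations to compute a degenerate-safe statistic
    (e.g. fewer than 4 lengths for IQR fences)."""


class SimulationError(NumtSieveError, RuntimeError):
    """The synthetic-community generator or a perturbation could not
    satisfy its constraints (e.g. unattainable GC target)."""
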