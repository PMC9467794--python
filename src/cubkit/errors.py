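"""Exception hierarchy shared across cubkit modules."""


class CubkitError(Exception):
    """Base class for all cubkit errors."""


class FormatError(CubkitError):
    """Malformed input file (FASTA, PHYLIP, config, weight table)."""


class ValidationError(CubkitError):
    """Input violates a documented precondition (frame, alphabet, spec)."""


class UndefinedStatisticError(CubkitError):
    """A statistic has no defined value for the given input.

    Raised instead of returning 0 or NaN so that "undefined" never
    silently contaminates downstream tables.
    """
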