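"""Exception hierarchy shared across the package."""


class TorsionError(Exception):
    """Base class for all package-specific errors."""


class StructureParseError(TorsionError):
    """A structure file could not be parsed."""


class EmptyStructureError(TorsionError):
    """A parsed file contains no RNA residues."""


class AlignmentError(TorsionError):
    """Two angle tables disagree in sequence at aligned positions."""


class NoOverlapError(TorsionError):
    """No aligned residue pair is available for comparison."""


class ContractError(TorsionError):
    """An operation was called with arguments violating its contract."""


class DegenerateInputError(TorsionError):
    """A statistic is undefined for the given input (e.g. zero variance)."""
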