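"""Exception hierarchy.

Everything raised on bad *data* derives from :class:`CDFTError`; the CLI maps
these to exit code 1, while argument/usage problems exit 2 (click's default).
"""


class CDFTError(Exception):
    """Base class for all data-level errors raised by cdftkit."""


class FormatError(CDFTError):
    """Malformed input file (missing column, truncated cube block, ...)."""


class InvariantError(CDFTError):
    """A domain invariant is violated (e.g. HOMO above LUMO)."""


class MissingDataError(CDFTError):
    """An operation needs data that was not supplied (e.g. ΔSCF without charge states)."""


class DegenerateHardnessError(CDFTError):
    """Hardness η ≤ 0: the descriptor algebra divides by η."""


class GridMismatchError(CDFTError):
    """Two scalar fields do not share origin/axes/shape within tolerance."""
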