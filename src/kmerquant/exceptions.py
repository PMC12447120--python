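"""Exception hierarchy for the pipeline.

All package errors derive from :class:`KmerQuantError` so callers can catch
everything with one clause; the subclasses distinguish bad user input
(files, configs) from contract violations inside the library.
"""


class KmerQuantError(Exception):
    """Base class for all errors raised by this package."""


class MaskFormatError(KmerQuantError):
    """A gapped-mask pattern string is syntactically or semantically invalid."""


class ValidationError(KmerQuantError):
    """Inputs are well-formed but violate a documented precondition."""


class InputError(KmerQuantError):
    """An input file is malformed or inconsistent (parse errors carry positions)."""


class ContractError(KmerQuantError):
    """An internal API was called with arguments violating its contract."""
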