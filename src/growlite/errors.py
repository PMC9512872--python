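"""Exception hierarchy shared across the package."""


class GrowliteError(Exception):
    """Base class for all package errors."""


class FormatError(GrowliteError):
    """A structure file could not be parsed."""


class InputError(GrowliteError):
    """Inputs violate a precondition (empty library, zero records, ...)."""


class ValenceError(GrowliteError):
    """An atom lacks the open valence an operation requires."""


class ContractError(GrowliteError):
    """Two objects that must be compatible are not (e.g. direction sets)."""


class SpecError(GrowliteError):
    """A fixture specification is out of its allowed range."""
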