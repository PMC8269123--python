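"""Exception hierarchy shared across the package."""


class MoanetError(Exception):
    """Base class for all package errors."""


class ValidationError(MoanetError):
    """Input violated a documented invariant (bad row, duplicate edge, ...)."""


class InputError(MoanetError):
    """A referenced entity (file, node, drug, pocket) does not exist."""
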