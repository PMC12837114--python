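class VsabciError(Exception):
    """Base class for package errors."""


class DomainError(VsabciError, ValueError):
    """A precondition on inputs or configuration was violated."""


class SessionFormatError(VsabciError, RuntimeError):
    """A session file on disk is malformed; message names the offending record."""
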