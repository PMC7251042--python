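"""Exception hierarchy."""


class MenisizeError(Exception):
    """Base class for all package errors."""


class ValidationError(MenisizeError, ValueError):
    """Invalid input data or parameters."""


class MeshIOError(MenisizeError, IOError):
    """Unreadable or unwritable mesh file."""


class DegenerateDataError(MenisizeError, ValueError):
    """Statistical input with no usable variance."""
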