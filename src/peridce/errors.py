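"""Exception hierarchy shared across the package."""


class PeridceError(Exception):
    """Base class for all package errors."""


class ValidationError(PeridceError, ValueError):
    """Invalid inputs, parameters, or violated invariants."""


class StructuralError(PeridceError, RuntimeError):
    """Malformed or inconsistent on-disk data (shape mismatches etc.)."""
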