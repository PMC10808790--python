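"""Exception hierarchy.

``SchemaError`` and ``NumericalError`` map onto the CLI exit codes 2 and 3.
"""


class CuspcatError(Exception):
    """Base class for all package errors."""


class SchemaError(CuspcatError):
    """Input table or configuration does not match the expected schema."""


class IdentifiabilityError(CuspcatError):
    """A model cannot be identified from the data (e.g. constant predictor)."""


class DegenerateDataError(CuspcatError):
    """Data admit no meaningful fit (e.g. zero outcome variance)."""


class NumericalError(CuspcatError):
    """A numerical routine failed to converge or produced non-finite values."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}
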