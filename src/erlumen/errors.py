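"""Package-wide error types with machine-parsable codes."""


class ErlumenError(Exception):
    """Base class; ``code`` is a stable machine-parsable identifier."""

    code = "ERR_GENERIC"

    def __str__(self) -> str:  # "CODE: message" on one line
        return f"{self.code}: {super().__str__()}"


class ValidationError(ErlumenError):
    code = "ERR_VALIDATION"


class FitError(ErlumenError):
    code = "ERR_FIT"


class NumericalError(ErlumenError):
    code = "ERR_NUMERIC"
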