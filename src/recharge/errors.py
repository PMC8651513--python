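"""Exception hierarchy."""


class RechargeError(Exception):
    """Base class for all package errors."""


class FormatError(RechargeError):
    """A required file structure (section, column) is missing."""


class ParseError(RechargeError):
    """A field could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line_number: int | None = None):
        super().__init__(message)
        self.line_number = line_number


class ValidationError(RechargeError):
    """An input violates a documented invariant."""


class ContractError(RechargeError):
    """A pluggable component does not satisfy its contract."""


class EssTooLowError(ValidationError):
    """Effective sample size fell below the configured floor.

    Signals that reweighted estimates are untrustworthy and fresh sampling
    is required ("resample required").
    """

    def __init__(self, ess: float, floor: float):
        super().__init__(
            f"effective sample size {ess:.2f} below floor {floor:.2f}: "
            "resample required"
        )
        self.ess = ess
        self.floor = floor
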