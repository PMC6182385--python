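"""Exception types shared across the package."""


class FrrfError(Exception):
    """Base class for all package errors."""


class DegenerateInput(FrrfError):
    """Input carries no usable signal (e.g. constant fluorescence trace)."""


class NonSaturatingTransient(FrrfError):
    """Induction rise did not plateau; fits are flagged rather than raised."""


class DivisionDegenerate(FrrfError):
    """A derived-parameter denominator is zero or otherwise degenerate."""


class ProtocolMismatch(FrrfError):
    """Measurements cannot be matched to the declared protocol."""


class NoRevisit(FrrfError):
    """No light level was visited more than once."""


class DegenerateX(FrrfError):
    """Regression predictor has zero variance."""


class FormatError(FrrfError):
    """A file does not conform to the documented column contract."""
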