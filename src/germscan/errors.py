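"""Exception types shared across the package."""


class GermscanError(Exception):
    """Base class for package errors."""


class ParameterError(GermscanError, ValueError):
    """A parameter violates an operation's precondition."""


class EstimationError(GermscanError, RuntimeError):
    """A data-driven estimate (mode, threshold) cannot be computed."""


class InputError(GermscanError, ValueError):
    """Invalid combination of user inputs (e.g. duplicate sequence ids)."""
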