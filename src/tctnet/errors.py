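"""Exception types shared across the package."""


class ShapeError(ValueError):
    """An array has a spatial/channel shape that violates an operation's contract."""


class ValidationError(ValueError):
    """An input value (not its shape) violates an operation's contract."""


class ContractError(RuntimeError):
    """An internal pre/post-condition between pipeline stages was violated."""
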