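"""Exception types shared across the package."""


class ValidationError(ValueError):
    """Invalid domain object, parameter value, or function argument."""


class SchemaError(ValueError):
    """A table read from disk does not satisfy the expected schema."""


class ConvergenceError(RuntimeError):
    """An iterative computation failed to reach its stopping criterion."""
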