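"""Exception types shared across the toolkit."""


class ValidationError(ValueError):
    """Raised when user-supplied data violates a documented contract
    (non-normalized probability rows, out-of-range labels, malformed tables)."""


class ContractViolationError(ValidationError):
    """Raised when a classifier object does not satisfy the stochastic
    forward-pass contract required by the requested operation."""


class UnsupportedTaskError(ValueError):
    """Raised when a closed-form quantity is requested for a task
    configuration it is not defined for (e.g. unequal class priors)."""
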