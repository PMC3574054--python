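"""Exception types shared across the pipeline."""


class DegenerateInputError(ValueError):
    """Input is formally valid but has no defined answer (e.g. zero resultant)."""


class OutOfDomainError(ValueError):
    """Evaluation requested outside a fitted domain (extrapolation forbidden)."""


class EstimationError(RuntimeError):
    """An estimator could not produce a usable result.

    Carries optional context (e.g. how many staircase reversals were found).
    """

    def __init__(self, message: str, **context):
        super().__init__(message)
        self.context = context


class NonIdentifiableError(EstimationError):
    """Data cannot constrain the model (e.g. all responses identical)."""
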