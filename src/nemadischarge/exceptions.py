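"""Exception types shared across the package."""


class DomainError(ValueError):
    """A physical parameter or argument lies outside its admissible domain."""


class ConvergenceError(ArithmeticError):
    """An iterative solver failed to converge.

    Attributes
    ----------
    residual : float or None
        Final residual (max norm) at the point of failure, when available.
    """

    def __init__(self, message, residual=None):
        super().__init__(message)
        self.residual = residual


class EjectionError(RuntimeError):
    """No static equilibrium exists: the applied pressure exceeds the fold.

    Attributes
    ----------
    threshold : float
        The fold (threshold) pressure beyond which the collar-stylet force
        balance has no solution and the stylet is ejected.
    """

    def __init__(self, message, threshold):
        super().__init__(message)
        self.threshold = threshold


class ClassificationError(ValueError):
    """A QCM series does not revisit any temperature often enough for the
    reversibility verdict to be defined."""
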