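"""Exception hierarchy for the inequality/inequity analysis chain.

Every error that can arise inside a single country's estimation is a
subclass of :class:`HequityError`, so the batch runner and the bootstrap
can isolate failures per group / per replicate without masking genuine
programming errors.
"""


class HequityError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(HequityError, ValueError):
    """A configuration parameter is outside its admissible range."""


class InvalidInputError(HequityError, ValueError):
    """Input data violate a precondition (empty vector, non-positive weight...)."""


class UndefinedIndexError(HequityError):
    """The requested index is undefined for these data (e.g. mean outcome is 0)."""


class DegenerateOutcomeError(UndefinedIndexError):
    """A binary outcome has no variation (prevalence exactly 0 or 1)."""


class UndefinedSEError(HequityError):
    """The analytic standard error cannot be computed (zero rank variance)."""


class CollinearityError(HequityError):
    """The design matrix is rank deficient; carries the aliased column names."""

    def __init__(self, aliased):
        self.aliased = list(aliased)
        super().__init__(f"design matrix is rank deficient; aliased columns: {self.aliased}")


class SeparationError(HequityError):
    """Perfect separation in the probit: the likelihood has no finite maximum."""

    def __init__(self, regressor):
        self.regressor = regressor
        super().__init__(
            f"perfect separation detected (diverging linear index); "
            f"most suspect regressor: {regressor!r}"
        )


class NotConvergedError(HequityError):
    """An operation requiring a converged fit was handed a non-converged one."""


class InferenceImpossibleError(HequityError):
    """All bootstrap replicates failed; no resampling inference is possible."""
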