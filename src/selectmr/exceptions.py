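"""Exception hierarchy for selectmr."""


class SelectMRError(Exception):
    """Base class for all selectmr errors."""


class FitError(SelectMRError):
    """A model fit failed (separation, non-convergence, singularity)."""

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace


class SeparationError(FitError):
    """Complete or quasi-complete separation in a binary-response fit."""


class ConvergenceError(FitError):
    """Optimizer failed to converge within the iteration budget."""


class CollinearityError(FitError):
    """Numerically collinear design; typically the selection instrument adds
    no exclusion information (inverse Mills ratio lies in the span of the
    outcome design)."""


class IdentificationError(FitError):
    """Flat or near-singular likelihood; parameters are not separably
    estimable (typically a weak or absent instrument for selection)."""


class ExtremeWeightError(FitError):
    """Inverse-probability weights exceed a numerical safety floor."""

    def __init__(self, message, rows=None):
        super().__init__(message)
        self.rows = rows


class ContractViolationError(SelectMRError):
    """An estimator was invoked with an invalid option combination (e.g.
    analytic 2SLS standard errors together with a selection adjustment)."""


class BootstrapError(SelectMRError):
    """Too many bootstrap resamples failed for the SD to be trusted."""
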