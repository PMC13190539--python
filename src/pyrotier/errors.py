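"""Exception hierarchy for the pyrotier pipeline."""


class PyrotierError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(PyrotierError):
    """Input table does not match the documented cohort schema."""


class EmptyCohortError(PyrotierError):
    """No valid records remain for analysis."""


class ConfigError(PyrotierError):
    """Invalid simulation or analysis configuration."""


class DegenerateMixtureError(PyrotierError):
    """Mixture fit collapsed (zero-variance component or vanishing weight)."""


class NoIntersectionError(PyrotierError):
    """Weighted component densities do not cross between the two means."""

    def __init__(self, message: str, density_ratio=None):
        super().__init__(message)
        self.density_ratio = density_ratio


class DesignError(PyrotierError):
    """Regression design is rank-deficient or mismatched with a fit."""


class NoEventsError(PyrotierError):
    """Survival data contain no observed events."""


class NoPairsError(PyrotierError):
    """No comparable pairs for concordance computation."""


class NoValidThresholdError(PyrotierError):
    """Every candidate cut-off produced a degenerate dichotomy."""


class InsufficientEventsError(PyrotierError):
    """Fewer events than cross-validation folds."""


class MissingPerCpGError(PyrotierError):
    """Per-CpG operation requested on a mean-only cohort."""


class DegenerateTestError(PyrotierError):
    """Log-rank variance is zero; groups have no comparable event structure."""


class UndefinedStatisticError(PyrotierError):
    """Statistic undefined (e.g. empty methylated mixture component)."""
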