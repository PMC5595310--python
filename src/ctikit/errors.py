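"""Exception hierarchy shared across the package."""


class CTIKitError(Exception):
    """Base class for all package errors."""


class FormatError(CTIKitError, ValueError):
    """An input file or table does not have the expected structure."""


class ValidationError(CTIKitError, ValueError):
    """Data violate a container invariant (duplicates, negatives, missing cells)."""


class AlignmentError(CTIKitError, ValueError):
    """Community and trait tables share no species."""


class CollinearityError(CTIKitError, ValueError):
    """Focal trait and a confounder are too strongly correlated to separate."""


class RankDeficiencyError(CTIKitError, ValueError):
    """The fixed-effects design matrix is not full rank."""


class ConvergenceError(CTIKitError, RuntimeError):
    """Likelihood optimisation did not converge within the iteration budget."""


class ScenarioError(CTIKitError, RuntimeError):
    """Too many replicate-level failures inside a simulation scenario."""
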