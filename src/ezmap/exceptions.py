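"""Exception hierarchy for the ezmap pipeline.

Every stage raises a subclass of :class:`EzMapError`; the CLI maps
configuration problems to exit code 2 and data problems to exit code 3.
"""


class EzMapError(Exception):
    """Base class for all ezmap errors."""


class ValidationError(EzMapError):
    """Invalid user-supplied parameters or inconsistent tabular inputs."""


class GridCompatibilityError(EzMapError):
    """Volumes do not share shape, voxel size, or mask geometry."""


class InsufficientCohortError(ValidationError):
    """Too few subjects for the requested statistic."""


class CollinearityError(ValidationError):
    """Degenerate (constant or collinear) covariate design."""


class ContractError(EzMapError):
    """An operation was called on an object whose metadata rules it out,
    e.g. Gaussian tail probabilities requested for a t-distributed map."""
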