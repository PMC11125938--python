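"""Exception types shared across the pipeline."""


class MammocycleError(Exception):
    """Base class for all package errors."""


class EmptyScanError(MammocycleError):
    """A volume contains no breast voxels (e.g. an all-water bath scan).

    Downstream this feeds the data-cleaning step rather than aborting a
    whole cohort run.
    """


class DegenerateDataError(MammocycleError):
    """Input is formally valid but carries no usable signal.

    Examples: all samples identical when clustering into k >= 2 classes,
    or a skin peel so deep that no interior is left.
    """


class InsufficientDataError(MammocycleError):
    """Fewer observations than the statistic requires (e.g. n < 2 for a CoV)."""


class ConfigurationError(MammocycleError):
    """Invalid or inconsistent user configuration."""
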