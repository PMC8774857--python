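"""Exception hierarchy for the MR screening pipeline."""


class MRScreenError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MRScreenError):
    """Invalid user configuration: missing columns, bad thresholds, misaligned inputs."""


class EmptyDatasetError(MRScreenError):
    """A summary-statistics table has no valid rows."""


class EmptyInstrumentError(MRScreenError):
    """Exposure and outcome share no usable variants."""


class DegenerateInstrumentError(MRScreenError):
    """A variant has a zero SNP-exposure effect, so its Wald ratio is undefined."""


class InsufficientVariantsError(MRScreenError):
    """A method needs more instrument variants than are available."""


class SingularFitError(MRScreenError):
    """A regression design is rank-deficient (e.g. identical SNP-exposure effects)."""
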