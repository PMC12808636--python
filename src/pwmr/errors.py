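"""Exception hierarchy for the pwmr pipeline."""


class PwmrError(Exception):
    """Base class for all pwmr errors."""


class ConfigurationError(PwmrError):
    """Invalid configuration: missing columns, bad thresholds, mismatched ids."""


class InputError(PwmrError):
    """Unusable input data: zero parseable rows, length mismatches."""


class HarmonizationError(PwmrError):
    """Exposure and outcome tables cannot be harmonized (e.g. empty intersection)."""


class EstimationError(PwmrError):
    """An MR estimator cannot run on the data it was given."""
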