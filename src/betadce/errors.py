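"""Exception hierarchy for betadce."""


class BetaDCEError(Exception):
    """Base class for all betadce errors."""


class ValidationError(BetaDCEError, ValueError):
    """Invalid argument or malformed input data."""


class FeatureLookupError(BetaDCEError, KeyError):
    """A requested feature id is not present in the matrix."""


class DegenerateFeatureError(BetaDCEError, ValueError):
    """A feature in the evaluated subset has zero variance."""


class SearchExhaustedError(BetaDCEError, RuntimeError):
    """The candidate pool cannot supply a subset of the requested size."""


class UndefinedAUCError(BetaDCEError, ValueError):
    """ROC AUC is undefined because only one class is present."""
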