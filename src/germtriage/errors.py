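"""Exception hierarchy shared across the pipeline."""


class GermtriageError(Exception):
    """Base class for all package errors."""


class ParseError(GermtriageError):
    """A record in an input file could not be parsed."""


class ContractViolation(GermtriageError):
    """An input violates a stated precondition or invariant."""


class ConfigError(GermtriageError):
    """Invalid configuration (thresholds, gene lists, weights)."""


class UndefinedFrequencyError(GermtriageError):
    """Allele frequency requested for an empty cohort."""


class DegenerateDataError(GermtriageError):
    """Statistical comparison is undefined for the given data."""
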