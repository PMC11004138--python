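"""Package exception hierarchy."""


class MiltsError(Exception):
    """Base class for all package errors."""


class MiltsInputError(MiltsError, ValueError):
    """Invalid user input (bad shapes, ranges, missing values)."""


class DegenerateDistributionError(MiltsInputError):
    """A distribution without enough spread to support the operation."""
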