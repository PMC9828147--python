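"""Exception types shared across the package."""


class DFinderError(Exception):
    """Base class for package-specific errors."""


class ParseError(DFinderError):
    """A delimited input file could not be parsed; the message names the line."""


class EmptyGraphError(DFinderError):
    """An operation that needs at least one node/edge got an empty graph."""


class CapacityError(DFinderError):
    """A sampling request exceeds the number of available items."""


class UndefinedMetricError(DFinderError):
    """A metric is undefined for the given label composition."""


class LeakageError(DFinderError):
    """Test edges were found in a structure that must only contain training data."""
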