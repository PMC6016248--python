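"""Exception hierarchy for relicdna."""


class RelicDNAError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(RelicDNAError, ValueError):
    """A parameter is outside its valid domain."""


class InsufficientIndividualsError(RelicDNAError, ValueError):
    """A draw or removal requests more individuals than a community holds."""


class UndefinedRatioError(RelicDNAError, ZeroDivisionError):
    """A ratio whose denominator is zero (empty intact pool, zero copies...)."""


class InvalidMatrixError(RelicDNAError, ValueError):
    """A distance matrix is not square, symmetric, non-negative, hollow."""


class FixtureParseError(RelicDNAError, ValueError):
    """A fixture file violates the tab-delimited dialect; message names the location."""
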