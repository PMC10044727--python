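"""Exception hierarchy shared across the pipeline stages."""


class LarvanetError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(LarvanetError):
    """A configuration object violates its invariants."""


class OutOfDomainError(LarvanetError):
    """A velocity query lies outside the field's spatial or temporal bounds."""


class CoverageError(LarvanetError):
    """The velocity field does not cover the requested simulation span."""


class SchemaError(LarvanetError):
    """A tabular input is malformed; message names the row and column."""


class EmptyReleaseError(LarvanetError):
    """A species occurs in zero MPAs, so no particles can be released."""


class ConsistencyError(LarvanetError):
    """Cross-stage inputs disagree (e.g. unknown MPA label in arrivals)."""
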