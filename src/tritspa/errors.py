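"""Exception hierarchy for tritspa.

All errors derive from :class:`TritspaError` so callers can catch the
package's failures with one clause; each subclass marks a distinct failure
mode (file format, record validation, count inconsistency, configuration).
"""


class TritspaError(Exception):
    """Base class for all tritspa errors."""


class FormatError(TritspaError):
    """An input file does not have the expected structure (e.g. a missing
    column in a records CSV)."""


class ValidationError(TritspaError):
    """A record violates a domain invariant (empty herb set, unknown
    outcome label, blank token)."""


class InconsistentCountsError(TritspaError):
    """A pair co-occurrence count exceeds the frequency of one of its
    members — impossible under record-level counting."""


class InsufficientDataError(TritspaError):
    """Not enough distinct observations to fit a distribution."""


class ConfigurationError(TritspaError):
    """A parameter set violates its constraints (simplex sums, ranges,
    infeasible pool sizes, missing entity types)."""
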