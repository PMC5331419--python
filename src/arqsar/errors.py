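"""Exception hierarchy for the arqsar package.

Load-time data problems raise distinct subclasses of :class:`TableLoadError`
so callers can tell a duplicate header from a missing cell without string
matching. Numerical failures (rank deficiency, degenerate penalties) get
their own classes because they signal modelling problems, not I/O problems.
"""


class ArqsarError(Exception):
    """Base class for all package errors."""


class TableLoadError(ArqsarError):
    """A table file could not be validated at load time."""


class DuplicateCompoundError(TableLoadError):
    """Duplicate compound identifiers in a table."""


class DuplicateDescriptorError(TableLoadError):
    """Duplicate descriptor names in a table header."""


class MissingValueError(TableLoadError):
    """A blank, non-numeric or non-finite cell where a number is required."""


class EmptyTableError(TableLoadError):
    """A table with no rows or no columns."""


class UnknownSplitError(TableLoadError):
    """A split label outside {train, pred_a, pred_b, screen}."""


class ModelSpecError(ArqsarError):
    """A model specification is malformed or inconsistent."""


class CurationError(ArqsarError):
    """Descriptor curation removed everything or was misconfigured."""


class SingularFitError(ArqsarError):
    """The regression design matrix is rank deficient."""


class DegeneratePenaltyError(ArqsarError):
    """Friedman LOF penalty denominator is zero or negative: (c + d*p) >= n."""


class DegenerateLOOError(ArqsarError):
    """A training point has leverage 1, so its LOO prediction is undefined."""


class DomainError(ArqsarError):
    """Applicability-domain computation failed (singular design, mismatch)."""


class ConfigError(ArqsarError):
    """Invalid run or GA configuration."""
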