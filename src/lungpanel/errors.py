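"""Exception hierarchy shared across the pipeline.

Exit-code mapping used by the CLI: validation/schema/integrity -> 2,
adjudication-incomplete -> 3, degenerate statistics -> 4.
"""


class LungPanelError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class SchemaError(LungPanelError):
    """A required column cannot be resolved in an input table."""

    exit_code = 2


class ValidationError(LungPanelError):
    """A row or value violates a domain invariant."""

    exit_code = 2


class IntegrityError(LungPanelError):
    """Structural inconsistency: duplicate ratings, wrong panel size."""

    exit_code = 2


class AdjudicationIncompleteError(LungPanelError):
    """An arbitrator rating required by the schema is absent."""

    exit_code = 3


class DegenerateStatisticsError(LungPanelError):
    """A statistic is undefined for the given table (e.g. constant raters)."""

    exit_code = 4


class TieError(LungPanelError):
    """Majority vote over an even number of iterations split exactly."""

    exit_code = 4
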