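"""Exception hierarchy.

Exit codes mirror the CLI contract: 2 for malformed input or schema
violations, 3 for unmet statistical preconditions, 4 for internal
energy-identity inconsistencies.
"""


class RegIQAError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class SchemaError(RegIQAError):
    """Malformed input: bad columns, labels, arities, duplicates."""

    exit_code = 2


class CompletenessError(SchemaError):
    """A term is present at some profile points but missing at others."""


class OrderingError(SchemaError):
    """Control coordinate not strictly monotonic over the point order."""


class PreconditionError(RegIQAError):
    """A statistical precondition is unmet (too few points, bad reference)."""

    exit_code = 3


class DegenerateSegmentError(PreconditionError):
    """Total energy has zero variance over the requested segment."""


class ConsistencyError(RegIQAError):
    """An exact energy identity is violated beyond tolerance."""

    exit_code = 4
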