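"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: validation errors -> 2,
infeasible/unbounded linear programs -> 3, numerical failures -> 4.
"""


class GlkError(Exception):
    """Base class for all package errors."""


class ValidationError(GlkError):
    """Malformed input: broken references, bad values, unparsable files."""


class StructuralError(ValidationError):
    """A network object violates its structural invariants."""


class InfeasibleProblem(GlkError):
    """A linear program has an empty feasible region."""


class UnboundedProblem(GlkError):
    """A linear program objective is unbounded over the feasible region."""


class NumericalError(GlkError):
    """A numerical procedure failed (singular system, rank collapse...)."""
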