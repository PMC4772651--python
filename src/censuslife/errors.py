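"""Exception hierarchy.

``ValidationError`` marks bad inputs (malformed files, inconsistent counts,
out-of-range parameters); ``ComputationError`` marks failures inside an
otherwise valid computation (singular matrices, degenerate eigenproblems,
runaway simulations). The CLI maps the two to distinct exit codes.
"""


class CensuslifeError(Exception):
    """Base class for all package errors."""


class ValidationError(CensuslifeError, ValueError):
    """Input data or configuration failed validation."""


class ComputationError(CensuslifeError, RuntimeError):
    """A numerical step failed on otherwise valid input."""
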