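"""Exception hierarchy for rvskill.

All package-specific failures derive from :class:`RVSkillError`, so callers
(including the CLI) can distinguish validation problems from genuine bugs or
I/O failures with a single ``except`` clause.
"""


class RVSkillError(Exception):
    """Base class for all rvskill errors."""


class FormatError(RVSkillError):
    """Input table does not have the expected structure (e.g. missing column)."""


class ParseError(RVSkillError):
    """A cell that must be numeric could not be parsed."""


class EmptyInputError(RVSkillError):
    """An input table or curve contains no data."""


class DegeneratePathError(RVSkillError):
    """A path is too short or geometrically degenerate for the operation."""


class AlignmentError(RVSkillError):
    """Paths do not share a common point count; resample before comparing."""


class DomainError(RVSkillError, ValueError):
    """A numeric argument lies outside its mathematical domain."""


class InsufficientDataError(RVSkillError):
    """Not enough checkpoints / repetitions to evaluate the requested rule."""
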