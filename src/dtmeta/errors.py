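"""Exception hierarchy used across the package."""


class DtmetaError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(DtmetaError):
    """An input table is missing mandatory columns or is otherwise malformed."""


class FormatError(DtmetaError):
    """A file (Newick tree, mapping table) could not be parsed."""


class UndefinedSlopeError(DtmetaError):
    """RMA slope undefined: one sex is invariant across treatments."""


class NegativeSlopeError(DtmetaError):
    """RMA slope is negative (sexes respond in opposite directions); its log is undefined."""


class BootstrapUnstableError(DtmetaError):
    """Too many bootstrap replicates yielded undefined slopes."""


class ResolutionError(DtmetaError):
    """Species-to-tree-tip resolution failed."""


class DegenerateModeratorError(DtmetaError):
    """Moderator has no variation; permutation inference is impossible."""


class FitError(DtmetaError):
    """Model fitting failed (singular design, too few effects, ...)."""


class PipelineError(DtmetaError):
    """A pipeline stage failed hard."""
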