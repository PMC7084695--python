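"""Exception hierarchy for the analyte-panel pipeline."""


class AAPanelError(Exception):
    """Base class for all package errors."""


class SchemaError(AAPanelError):
    """A required column is missing or the column mapping is inconsistent."""


class ValidationError(AAPanelError):
    """Input data violates a panel invariant (e.g. negative concentration)."""


class EmptyPanelError(AAPanelError):
    """An operation left the panel without any analytes."""


class DegenerateDesignError(AAPanelError):
    """The fitting problem is degenerate (single class present)."""


class RankDeficiencyError(AAPanelError):
    """A design column carries no information (constant-valued analyte)."""


class FoldError(AAPanelError):
    """Cross-validation folds cannot be constructed as requested."""


class IterationError(AAPanelError):
    """A cross-validation iteration cannot be run (e.g. one-class training fold)."""


class ConfigurationError(AAPanelError):
    """A configuration object is internally inconsistent."""


class UndefinedRocError(AAPanelError):
    """ROC analysis is undefined (labels contain a single class)."""
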