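"""Exception hierarchy shared across the pipeline."""


class MetaboMrError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MetaboMrError):
    """A configuration problem: missing column, missing file, bad parameter."""


class ValidationError(MetaboMrError):
    """Input data violate a declared invariant (bad eaf, se <= 0, duplicates...)."""


class DegenerateInputError(MetaboMrError):
    """An operation was handed input on which its formula is undefined."""


class InsufficientInstrumentsError(MetaboMrError):
    """Fewer variants than the estimator's minimum."""


class LdLookupError(MetaboMrError):
    """The LD source has no r-squared for a pair the clumping rule needs."""


class PipelineError(MetaboMrError):
    """A pipeline stage failed; the message names the stage and exposure."""
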