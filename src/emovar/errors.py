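"""Exception hierarchy shared across the pipeline stages."""


class EmovarError(Exception):
    """Base class for all package errors."""


class LexiconError(EmovarError):
    """Lexicon file invalid: missing or non-positive base rate, empty
    emotion set, malformed entries."""


class UnscorableDocument(EmovarError):
    """Document tokenizes to zero tokens; the linguistic score is undefined."""


class EmptySeriesError(EmovarError):
    """No scorable documents at all; the daily series would be empty."""


class GapError(EmovarError):
    """A requested week has no data in one of the sources."""

    def __init__(self, week: int, source: str):
        self.week = week
        self.source = source
        super().__init__(f"week {week} has no data in source '{source}'")


class TrendsLoadError(EmovarError):
    """Behavior index file malformed; carries the offending row number."""


class DegenerateColumnError(EmovarError):
    """A panel column has zero sample variance."""


class EstimationError(EmovarError):
    """Least-squares estimation infeasible: rank-deficient regressors or
    too few rows."""


class StabilityError(EmovarError):
    """An operation required a stable VAR but the point estimate is not."""


class InfeasibleTargetError(EmovarError):
    """A latent emotion target implies a token-match probability outside
    [0, 1] (or probabilities summing above 1)."""


class PipelineError(EmovarError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
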