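"""Exception hierarchy shared across the pipeline."""


class EgfrSigError(Exception):
    """Base class for all pipeline errors."""


class ConfigError(EgfrSigError):
    """Invalid simulation or analysis configuration."""


class InputError(EgfrSigError):
    """Malformed or out-of-range input data."""


class ScoringError(EgfrSigError):
    """Gene-set scoring cannot proceed (empty overlap, degenerate set)."""


class PipelineError(EgfrSigError):
    """A pipeline stage produced an unusable result (e.g. all cells filtered)."""


class FitError(EgfrSigError):
    """Model fitting or evaluation failed."""
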