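"""Exception types shared across the pipeline."""


class ClipseedError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(ClipseedError, ValueError):
    """Invalid user-supplied configuration (probabilities, counts, ...)."""


class GenerationError(ClipseedError, RuntimeError):
    """A bounded stochastic generation procedure exhausted its retries."""


class PlantingError(ClipseedError, RuntimeError):
    """A target site could not be planted into a 3'UTR."""


class EstimationError(ClipseedError, RuntimeError):
    """A statistical fit failed (non-convergence, degenerate input)."""
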