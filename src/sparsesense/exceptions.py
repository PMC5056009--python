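"""Exception hierarchy used across the package."""


class SparseSenseError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(SparseSenseError, ValueError):
    """Invalid parameter or configuration value (bad enum, negative scale, ...)."""


class DataError(SparseSenseError, ValueError):
    """Inconsistent array shapes or otherwise invalid input data."""


class FormatError(SparseSenseError, ValueError):
    """Malformed dataset container (missing dataset/attribute)."""


class DivergenceError(SparseSenseError, RuntimeError):
    """A solver produced a non-finite iterate.

    Carries the iteration index at which divergence was detected and the
    history accumulated up to that point.
    """

    def __init__(self, iteration: int, history=None):
        super().__init__(f"solver iterate became non-finite at iteration {iteration}")
        self.iteration = iteration
        self.history = history if history is not None else []
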