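"""Exception hierarchy for fissim."""


class FissimError(Exception):
    """Base class for all fissim errors."""


class ConfigurationError(FissimError, ValueError):
    """A parameter set violates a model constraint (e.g. the feasibility
    bound (lambda1 + lambda2) <= 1 - C*100, or a transfer percentage
    outside [0, 100])."""


class UndefinedRatioError(ConfigurationError):
    """The Nutrition/Sociality ratio is undefined (mimetic coefficient C = 0)."""


class SimulationError(FissimError, RuntimeError):
    """A simulation failed to make progress (e.g. the daily movement loop
    exceeded its round limit because nobody can ever leave the resting
    area)."""


class InsufficientDataError(FissimError, ValueError):
    """A statistical routine was given too few points or levels."""
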