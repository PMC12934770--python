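"""Exception types shared across the package."""


class ParameterError(ValueError):
    """A parameter is outside its documented range."""


class MissingDataError(ValueError):
    """Required input data are absent or empty."""


class ConfigurationError(ValueError):
    """A configuration is internally inconsistent."""


class NumericalInstabilityError(RuntimeError):
    """Integration produced non-finite values."""


class FitFailureError(RuntimeError):
    """Every optimisation start failed to converge."""


class InfeasibleScheduleError(ValueError):
    """A phase schedule admits no positive-parameter solution."""
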