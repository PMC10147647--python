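"""Exception types shared across the package."""


class InvalidSpecError(ValueError):
    """A simulation/degradation specification violates its constraints."""


class OutOfRangeError(ValueError):
    """A reflector lies beyond the unambiguous imaging depth of the axis."""


class ConfigurationError(ValueError):
    """A processing configuration is unusable (e.g. STFT hop rounds to zero)."""


class CalibrationError(RuntimeError):
    """Iterative calibration failed to converge."""


class MeasurementError(RuntimeError):
    """A resolution measurement could not be completed on the given profile."""
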