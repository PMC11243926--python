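"""Exception hierarchy for the temperature-extraction pipeline.

Every failure mode a frame can hit maps to one subclass so callers can
record a per-detection status instead of aborting the whole frame.
"""


class LizardthermError(Exception):
    """Base class for all package errors."""


class BoundsError(LizardthermError):
    """A rectangle or scale-bar footprint extends past the image edge."""


class InputError(LizardthermError):
    """A source file is missing or cannot be decoded."""


class DetectorError(LizardthermError):
    """The detector backend failed; carries the backend identity."""

    def __init__(self, backend: str, message: str):
        self.backend = backend
        super().__init__(f"detector backend {backend!r}: {message}")


class NoForegroundError(LizardthermError):
    """A bounding box contains no foreground (white) pixel after thresholding."""


class SingularQuadError(LizardthermError):
    """The four-point correspondence is degenerate (three points collinear)."""


class MappingError(LizardthermError):
    """A point maps to infinity (homogeneous w = 0) under the homography."""


class OutOfPanelError(LizardthermError):
    """A mapped pixel lands outside the thermal panel; carries raw coordinates."""

    def __init__(self, raw_x: float, raw_y: float):
        self.raw_x = raw_x
        self.raw_y = raw_y
        super().__init__(
            f"mapped point ({raw_x:.3f}, {raw_y:.3f}) falls outside the thermal panel"
        )


class RangeError(LizardthermError):
    """A scale-bar row lies outside [y_min, y_max]."""


class ConfigError(LizardthermError):
    """Required configuration keys are missing; lists them."""

    def __init__(self, missing_keys):
        self.missing_keys = list(missing_keys)
        super().__init__(f"missing config keys: {', '.join(self.missing_keys)}")
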