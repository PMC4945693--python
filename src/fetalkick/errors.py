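"""Exception types shared across the pipeline stages."""


class FetalKickError(Exception):
    """Base class for all package errors."""


class ConfigurationError(FetalKickError):
    """A scenario or config is geometrically or physically inconsistent."""


class ParseError(FetalKickError):
    """A fixture or config file could not be parsed; names the offending field."""


class DegenerateMatchError(FetalKickError):
    """Template matching attempted on a zero-variance template or region."""


class TrackLostError(FetalKickError):
    """No admissible template-match candidate for a joint on a frame."""

    def __init__(self, joint: str, frame: int, message: str = ""):
        self.joint = joint
        self.frame = frame
        super().__init__(
            f"track lost for joint '{joint}' at frame {frame}"
            + (f": {message}" if message else "")
        )


class MeshError(FetalKickError):
    """Mesh construction failed (resolution too coarse, inverted element, ...)."""


class ConvergenceError(FetalKickError):
    """Newton iteration failed to converge."""

    def __init__(self, increment: int, residual: float):
        self.increment = increment
        self.residual = residual
        super().__init__(
            f"Newton solver did not converge at increment {increment} "
            f"(relative residual {residual:.3e})"
        )
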