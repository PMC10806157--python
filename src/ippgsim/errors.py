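"""Exception hierarchy shared across the simulator and extraction suite."""


class IPPGSimError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(IPPGSimError, ValueError):
    """A parameter is outside its documented valid range."""


class DegenerateSignalError(IPPGSimError, ValueError):
    """A signal is constant / empty where variation is required."""


class AliasingError(InvalidParameterError):
    """Sampling rate too low for the requested oscillation frequency."""


class ShapeError(IPPGSimError, ValueError):
    """Array lengths or shapes are inconsistent."""


class ResampleRequiredError(IPPGSimError, ValueError):
    """A signal's sampling rate does not match the video frame rate."""


class NoPulseFoundError(IPPGSimError, RuntimeError):
    """No decomposition component met the pulse-selection rule."""
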