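"""Exception hierarchy shared across the package."""


class RootQuantError(Exception):
    """Base class for all package errors."""


class ValidationError(RootQuantError, ValueError):
    """Invalid argument values, geometries, or configurations."""


class ImageIOError(RootQuantError, IOError):
    """Unreadable or unsupported image files."""


class PlacementError(RootQuantError):
    """Synthetic scene generation could not reach the requested colonization.

    Carries the fraction that was actually achieved so callers can decide
    whether to relax the target.
    """

    def __init__(self, target: float, achieved: float, message: str | None = None):
        self.target = float(target)
        self.achieved = float(achieved)
        if message is None:
            message = (
                f"could not place structures for target colonization "
                f"{target:.3f}; achieved {achieved:.3f}"
            )
        super().__init__(message)


class ModelConfigMismatch(RootQuantError):
    """A model was asked to predict with an incompatible feature config."""


class ModelVersionError(RootQuantError):
    """A stored model file has an unsupported version tag."""
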