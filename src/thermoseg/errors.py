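"""Exception hierarchy for thermoseg.

Every anticipated failure mode raises a subclass of :class:`ThermosegError`
so callers can catch package errors without masking genuine bugs.
"""


class ThermosegError(Exception):
    """Base class for all thermoseg errors."""


class ParameterError(ThermosegError, ValueError):
    """An argument is outside its documented domain."""


class ImageReadError(ThermosegError, IOError):
    """A file could not be read or decoded as an image."""


class EmptySceneError(ThermosegError):
    """A binary mask contains no foreground to segment."""


class AmbiguousSceneError(ThermosegError):
    """More usable foreground components than the pipeline can attribute."""


class InitializationError(ThermosegError):
    """Contour initialization failed for one breast side."""


class SnakeCollapseError(ThermosegError):
    """The active contour collapsed to a degenerate area."""


class EmptyRegionError(ThermosegError):
    """A feature was requested over an empty region."""


class DegenerateGLCMError(ThermosegError):
    """No valid pixel pair exists for the requested co-occurrence offset."""


class PairingError(ThermosegError, ValueError):
    """Left/right feature lists cannot be paired."""


class AssemblyError(ThermosegError):
    """A feature block required to assemble the vector is missing."""


class StratificationError(ThermosegError, ValueError):
    """A class has too few samples for a stratified split."""


class DegenerateTrainingError(ThermosegError, ValueError):
    """The training set does not contain both classes."""


class PhantomSpecError(ThermosegError, ValueError):
    """A synthetic phantom specification is geometrically infeasible."""
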