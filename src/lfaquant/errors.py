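"""Exception hierarchy for the lateral-flow quantification pipeline.

Every error raised by this package derives from :class:`LFAError`, so callers
can catch pipeline failures without masking programming errors.
"""


class LFAError(Exception):
    """Base class for all lfaquant errors."""


class DomainError(LFAError, ValueError):
    """An input value is outside the mathematical domain of an operation
    (e.g. a negative concentration passed to a forward calibration model)."""


class InvalidModelError(LFAError, ValueError):
    """A calibration model violates its parameter constraints
    (e.g. a four-parameter logistic with a non-positive inflection)."""


class GeometryError(LFAError, ValueError):
    """A region of interest or strip geometry is degenerate or out of bounds."""


class FormatError(LFAError, ValueError):
    """An image raster has an unsupported shape, channel count, or dtype."""


class ConfigError(LFAError, ValueError):
    """A configuration document or parameter set failed validation."""


class RenderSaturationError(LFAError, ValueError):
    """A simulated strip would clip its line troughs at zero intensity;
    such an image is unquantifiable and the simulator refuses to produce it."""


class MissingLineError(LFAError, RuntimeError):
    """Fewer reagent lines than expected were detected on the profile.

    ``which`` names the line region lacking a peak ("test", "control" or
    "both").
    """

    def __init__(self, which: str, message: str | None = None):
        self.which = which
        super().__init__(message or f"no qualifying minimum in the {which} line region")


class InvalidStripError(LFAError, RuntimeError):
    """The strip failed its internal validity check (control line absent or
    weaker than the minimum acceptable depth): the run must be repeated."""


class SingularFitError(LFAError, ValueError):
    """The calibration design matrix is singular (e.g. a single distinct
    concentration), so no unique fit exists."""


class InputError(LFAError, ValueError):
    """Evaluation inputs are empty or have mismatched lengths."""


class UndefinedROCError(LFAError, ValueError):
    """An ROC analysis was requested on a cohort containing only one class."""
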