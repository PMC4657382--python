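"""Exception hierarchy for femcurve.

All errors raised by the library derive from :class:`FemcurveError` so callers
can catch one base class; subclasses mirror the failure modes of the pipeline
stages (bad parameters, bad input meshes, geometric degeneracies, contact
failures during pose standardization, and per-stage pipeline errors).
"""


class FemcurveError(Exception):
    """Base class for all femcurve errors."""


class ParameterError(FemcurveError, ValueError):
    """A parameter value is outside its documented domain."""


class InputError(FemcurveError, ValueError):
    """An input object (mesh, table) violates a precondition."""


class SectionError(FemcurveError):
    """A slicing plane produced no usable cross-section."""


class ExtractionError(FemcurveError):
    """Centerline extraction failed (too many empty slices)."""


class DegeneracyError(FemcurveError):
    """Geometric degeneracy: collinear points, vanishing directions."""


class SettlingError(FemcurveError):
    """No stable resting face found on the convex hull."""


class ContactError(FemcurveError):
    """Distal contact conditions cannot be met (single support point)."""


class StateError(FemcurveError):
    """Operation called on an object in the wrong state."""


class ConfigError(FemcurveError, ValueError):
    """Pipeline run configuration is invalid."""


class FitWarning(UserWarning):
    """Geometric refinement did not converge; algebraic result returned."""


class PipelineStageError(FemcurveError):
    """A pipeline stage failed; carries the stage tag and the original error."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}' failed: {cause!r}")
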