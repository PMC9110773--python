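"""Exception hierarchy.

All errors raised by lvmass derive from :class:`LvmassError` so callers can
catch the package's failures with a single except clause.  The subclasses
mirror the stages of the workflow: contour/geometry handling, method
feasibility, statistical analysis, cohort simulation and file I/O.
"""


class LvmassError(Exception):
    """Base class for all lvmass errors."""


class ContourError(LvmassError):
    """Invalid traced contour (too few points, self-intersection, zero area,
    missing or inconsistent base landmarks)."""


class GeometryError(LvmassError):
    """Geometric contract violation (zero-length axis, truncation beyond the
    semi-axis, mismatched disk stacks, non-positive linear dimension)."""


class TracingError(LvmassError):
    """Physiologically inconsistent tracings (epicardial area not exceeding
    endocardial area, non-positive wall thickness, epi volume <= endo volume)."""


class AnalysisError(LvmassError):
    """Statistical contract violation (sample too small, degenerate or
    constant series, subject mismatch between readings)."""


class CalibrationError(LvmassError):
    """Synthetic-cohort targets unreachable from the shape priors."""


class ValidationError(LvmassError):
    """Malformed study file; the message names the offending field/record."""
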