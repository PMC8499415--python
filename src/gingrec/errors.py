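"""Exception hierarchy for gingrec."""


class GingrecError(Exception):
    """Base class for all package-specific errors."""


class MeshFormatError(GingrecError):
    """Unreadable or truncated mesh file."""


class EmptyMeshError(GingrecError):
    """Mesh contains no faces."""


class NoIntersectionError(GingrecError):
    """Slicing plane does not intersect the mesh."""


class DegenerateSectionError(GingrecError):
    """Cross-section chain too short to be usable (< 3 points)."""


class DegenerateInputError(GingrecError):
    """Too few points/samples for the requested curve operation."""


class LandmarkNotFoundError(GingrecError):
    """No qualifying curvature transition for the requested landmark.

    Carries ``candidates``: diagnostics for the closest rejected segments.
    """

    def __init__(self, message, candidates=None):
        super().__init__(message)
        self.candidates = candidates or []


class OrientationError(GingrecError):
    """Detected GM is coronal to the detected CEJ."""


class OffCurveError(GingrecError):
    """A manual pick lies too far from the section curve."""


class ConstructionError(GingrecError):
    """Synthetic profile spec is geometrically unsatisfiable."""


class InputError(GingrecError):
    """Malformed tabular input (duplicates, missing cells, length mismatch)."""
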