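"""Exception hierarchy for the HTO planning toolkit."""


class Hto3dError(Exception):
    """Base class for all toolkit errors."""


class MeshFormatError(Hto3dError):
    """A mesh file could not be parsed (truncated, wrong magic, bad layout)."""


class ValidationError(Hto3dError):
    """An object violates a structural invariant (empty mesh, bad range...)."""


class LandmarkError(Hto3dError):
    """A required named landmark is missing or malformed."""

    def __init__(self, missing, message=None):
        if isinstance(missing, str):
            missing = [missing]
        self.missing = list(missing)
        super().__init__(message or f"missing required landmark(s): {', '.join(self.missing)}")


class DegenerateFrameError(Hto3dError):
    """Frame-defining landmarks are (near-)collinear or coincident."""


class DegeneracyError(Hto3dError):
    """A projected direction collapsed below the usable length threshold."""


class RangeError(Hto3dError):
    """A requested level or crop lies outside the mesh extent."""


class PlanningError(Hto3dError):
    """Osteotomy construction failed (entry point off cortex, hinge outside bone...)."""


class GeometryError(Hto3dError):
    """No valid opening-angle solution exists for the requested gap."""


class TopologyError(Hto3dError):
    """The cuts did not separate the bone into the expected fragments."""

    def __init__(self, n_components, message=None):
        self.n_components = n_components
        super().__init__(message or f"cut produced {n_components} fragment(s), expected 2")


class OrientationError(Hto3dError):
    """A mesh does not have consistently oriented face normals."""


class InsufficientDataError(Hto3dError):
    """Too few observations for the requested statistic."""
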