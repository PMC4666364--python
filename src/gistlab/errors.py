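"""Exception hierarchy."""


class GistLabError(Exception):
    """Base class for all package errors."""


class ParseError(GistLabError):
    """Malformed input file; carries the offending line number when known."""

    def __init__(self, message, line_number=None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class EmptyInputError(GistLabError):
    """Input contained no atoms/frames."""


class MissingParameterError(GistLabError):
    """Force-field parameters missing for one or more atoms."""


class SelectionError(GistLabError):
    """Invalid or (disallowed) empty atom selection."""


class EmptySystemError(GistLabError):
    """An operation would leave no atoms in the system."""


class StructureError(GistLabError):
    """Chemically inconsistent structure (e.g. water without hydrogens)."""


class GeometryError(GistLabError):
    """Degenerate geometry (e.g. coincident distinct atoms)."""


class SurfaceError(GistLabError):
    """Shell-surface construction produced no points."""


class EmptyRegionError(GistLabError):
    """Region contains no voxels or no water."""


class GeneratorError(GistLabError):
    """Synthetic ensemble specification is unrealizable."""


class IncompatibleError(GistLabError):
    """Two results cannot be compared (different references)."""
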