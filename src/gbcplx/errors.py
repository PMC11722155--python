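"""Exception hierarchy."""


class GbcplxError(Exception):
    """Base class for all package errors."""


class PQRParseError(GbcplxError, ValueError):
    """Malformed PQR/PQG record."""


class EmptyInputError(GbcplxError, ValueError):
    """A structure file contained no atoms."""


class ChainSelectionError(GbcplxError, ValueError):
    """Invalid chain partition (overlap, or chain absent from the file)."""


class AlignmentError(GbcplxError, ValueError):
    """Per-atom arrays do not line up with the entity's atoms."""


class ResolutionError(GbcplxError, ValueError):
    """Degenerate surfacing grid."""


class MeshIntegrityError(GbcplxError, ValueError):
    """Extracted mesh is not closed."""


class MeshFormatError(GbcplxError, ValueError):
    """Malformed external surface file (.vert/.face)."""


class GeometryError(GbcplxError, ValueError):
    """Coincident points or other degenerate geometry."""


class ConfigurationError(GbcplxError, ValueError):
    """Inconsistent run configuration (model or probe mismatch)."""


class StateError(GbcplxError, RuntimeError):
    """An operation was called before its prerequisites were computed."""


class DegenerateDataError(GbcplxError, ValueError):
    """Statistic undefined on the given data (zero variance, too few points)."""
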