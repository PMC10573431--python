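"""Exception hierarchy shared across the package."""


class OpReactError(Exception):
    """Base class for all package-specific errors."""


class PDBParseError(OpReactError):
    """A PDB file could not be parsed or contained no atoms."""


class AtomLookupError(OpReactError, LookupError):
    """An atom selection matched no atom."""


class AmbiguousSelectionError(OpReactError):
    """An atom selection matched more than one atom."""


class SchemaError(OpReactError):
    """A tabular input is missing required columns."""


class GeometryError(OpReactError, ValueError):
    """Degenerate geometry (coincident points, zero-length vectors)."""


class ClassificationError(OpReactError, ValueError):
    """A substituent token is outside the controlled vocabulary."""
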