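"""Exception hierarchy shared across the package."""


class PepforgeError(Exception):
    """Base class for all package-specific errors."""


class PDBFormatError(PepforgeError):
    """Raised when PDB text cannot be parsed or written."""


class GeometryError(PepforgeError):
    """Raised for degenerate or mismatched coordinate input."""


class LibraryError(PepforgeError):
    """Raised for library construction / serialization problems."""


class BuildError(PepforgeError):
    """Raised when conformer assembly cannot produce a clash-free chain."""


class EvaluationError(PepforgeError):
    """Raised for invalid ensemble/reference comparisons."""
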