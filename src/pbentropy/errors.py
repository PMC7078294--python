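"""Exception hierarchy."""


class PBEntropyError(Exception):
    """Base class for all package errors."""


class PdbParseError(PBEntropyError):
    """A PDB coordinate line could not be interpreted."""


class EmptyEnsembleError(PBEntropyError):
    """A file or ensemble contains no usable models."""


class UnrecoverableEnsembleError(PBEntropyError):
    """Model residue sequences are mutually inconsistent; no majority exists."""


class GeometryError(PBEntropyError):
    """Degenerate geometry (coincident or collinear points)."""


class ConsistencyError(PBEntropyError):
    """Inputs that must agree (lengths, chains) do not."""


class SpecError(PBEntropyError):
    """An ensemble/region specification violates its invariants."""
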