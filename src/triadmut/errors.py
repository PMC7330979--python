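"""Exception hierarchy.

Every error raised by the package derives from :class:`TriadmutError` so
callers can catch the whole family with one clause.
"""


class TriadmutError(Exception):
    """Base class for all package errors."""


class StructureError(TriadmutError):
    """Problems reading, cleaning or writing a coordinate model."""


class MissingChainError(StructureError):
    """A requested chain id is absent from the file."""


class EmptyStructureError(StructureError):
    """No residues survive cleaning (or an empty model was given)."""


class IncompleteTriadError(TriadmutError):
    """A triad pair is missing one of its 24 main-chain atoms."""


class DegenerateGeometryError(TriadmutError):
    """Too few or collinear points: superposition is ill-conditioned."""


class DegenerateSpectrumError(TriadmutError):
    """SVD of an all-zero signature matrix was requested."""


class DimensionError(TriadmutError):
    """Vector/model feature-length mismatch."""


class ConfigError(TriadmutError):
    """Invalid parameter value or unknown configuration key."""


class DatabaseError(TriadmutError):
    """Corrupt or incomplete persisted database."""


class ProvenanceError(TriadmutError):
    """A proposal does not originate from the given structure/database."""


class DegenerateTestError(TriadmutError):
    """A paired t-test was requested on zero-variance differences."""


class InfeasibleFixtureError(TriadmutError):
    """A planted interaction cannot be realised at the requested geometry."""
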