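"""Exception hierarchy shared by all nlsgeom modules."""


class NlsGeomError(Exception):
    """Base class for all package errors."""


class FormatError(NlsGeomError):
    """Input file is empty, truncated or not in the expected format."""


class IntegrityError(NlsGeomError):
    """Parsed structure violates a uniqueness or consistency constraint."""


class LookupError_(NlsGeomError):
    """A requested chain/residue/atom does not exist."""


class GeometryError(NlsGeomError):
    """A geometric operation received degenerate or insufficient input."""


class OccupancyError(NlsGeomError):
    """A binding site is unoccupied: no peptide residue sits in the pocket."""


class StatisticsError(NlsGeomError):
    """Too few observations to compute the requested statistic."""


class ContractError(NlsGeomError):
    """Arguments violate an operation's calling contract."""


class ConstructionError(NlsGeomError):
    """A synthetic-geometry request is infeasible."""


class AlignmentError(NlsGeomError):
    """Sequence correspondence could not be established (coverage too low)."""
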