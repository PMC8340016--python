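"""Exception hierarchy shared across modules."""


class GrpsigError(Exception):
    """Base class for all library errors."""


class OntologyStructureError(GrpsigError):
    """The term DAG violates a structural requirement (cycle, orphan term,
    term reachable from more than one category root)."""


class CategoryMismatchError(GrpsigError):
    """Two meaning sets from different GO categories were combined."""


class DataValidationError(GrpsigError):
    """An input table violates its contract (duplicate IDs, bad event codes,
    negative times, zero shared samples...)."""


class DegenerateInputError(GrpsigError):
    """The computation is undefined for this input (constant expression
    submatrix, zero events, identical scores, empty pool...)."""
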