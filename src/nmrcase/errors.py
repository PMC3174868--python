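"""Exception hierarchy shared by all stages of the pipeline.

Each CLI subcommand maps these onto distinct exit codes; library users can
catch :class:`NmrCaseError` to handle any domain failure.
"""


class NmrCaseError(Exception):
    """Base class for all domain errors raised by this package."""


class FormulaError(NmrCaseError):
    """Molecular formula cannot be parsed or is chemically inconsistent."""


class ConstitutionError(NmrCaseError):
    """A molecular graph violates valence, connectivity or bond-order rules."""


class CorrelationError(NmrCaseError):
    """A correlation list references unknown atoms or impossible proton counts."""


class ContradictionError(CorrelationError):
    """Two correlations on the same atom pair admit no common path length."""


class InfeasibleError(NmrCaseError):
    """Inputs admit no constitution at all; detected before the search starts."""


class OracleLimitError(NmrCaseError):
    """Brute-force enumeration refused: problem exceeds its size limit."""


class EmptyCorpusError(NmrCaseError):
    """No reference molecule could be parsed; a filter built from nothing
    would silently eliminate every candidate."""


class InputError(NmrCaseError):
    """An input document fails schema validation or cross-reference checks."""
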