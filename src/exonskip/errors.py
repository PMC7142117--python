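"""Exception hierarchy shared across the toolkit."""


class ExonSkipError(Exception):
    """Base class for all toolkit errors."""


class CoordinateError(ExonSkipError, ValueError):
    """A position falls outside the coordinate range it was interpreted in."""


class NotExonicError(CoordinateError):
    """A genomic position does not fall inside any exon of the transcript."""


class ReferenceMismatchError(ExonSkipError, ValueError):
    """The stated reference allele disagrees with the transcript sequence."""


class NoCodingEffectError(ExonSkipError, ValueError):
    """The requested skip event does not touch the coding sequence."""


class UnsupportedConsequenceError(ExonSkipError, ValueError):
    """The skip event produces a consequence outside the supported model
    (e.g. loss of the start codon)."""


class AlphabetError(ExonSkipError, ValueError):
    """A nucleotide string contains characters outside {A, C, G, T}."""


class MotifFormatError(ExonSkipError, ValueError):
    """A motif file line does not parse as a k-mer of the declared length."""


class UndefinedOddsRatioError(ExonSkipError, ValueError):
    """Both cross products of a 2x2 table are zero; the odds ratio is 0/0."""


class DegenerateModelError(ExonSkipError, ValueError):
    """Prevalence-model parameters at the boundary of the open domain."""


class EvidenceError(ExonSkipError, ValueError):
    """Invalid ACMG evidence list (duplicate code or strength upgrade)."""


class ConstraintError(ExonSkipError, ValueError):
    """A simulation request cannot be satisfied by any output."""
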