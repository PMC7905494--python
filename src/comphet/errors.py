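"""Exception hierarchy for the comphet toolkit."""


class CompHetError(Exception):
    """Base class for all toolkit errors."""


class VcfParseError(CompHetError):
    """A VCF data line could not be parsed (message names the line number)."""


class VcfOrderError(CompHetError):
    """Records are not sorted by (contig, position) and no sort was requested."""


class PedigreeError(CompHetError):
    """The PED file defines no usable trio, or the parentage is inconsistent."""


class HarmonizationError(CompHetError):
    """Trio harmonization received an empty or unusable child record set."""


class MergeConflictError(CompHetError):
    """Trio members disagree on the REF allele at an identical locus."""


class ConcatenationError(CompHetError):
    """Per-chromosome record sets overlap or are internally inconsistent."""


class ContractViolationError(CompHetError):
    """A genotype outside the biallelic index range reached a biallelic-only step."""


class CoordinateError(CompHetError):
    """A locus lies beyond the end of its reference contig."""


class NormalizationError(CompHetError):
    """Variant normalization preconditions violated (REF mismatch, or
    left-extension required at position 1)."""


class AnnotationParseError(CompHetError):
    """A SnpEff-style ANN entry has too few pipe-delimited fields."""


class ModeError(CompHetError):
    """A trio-only analysis (compound het, de novo) was requested without a trio."""


class TableParseError(CompHetError):
    """A GDI or gene-length table row is malformed."""


class PlanError(CompHetError):
    """A synthetic-fixture plan is internally contradictory."""
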