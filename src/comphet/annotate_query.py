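"""Ingestion of SnpEff-style ANN annotations into a queryable variant store.

Each VCF record carrying an ``ANN`` INFO field yields one
:class:`AnnotatedVariant` per gene named in its annotation entries; a
variant overlapping *k* genes yields *k* entries and may be considered in
each gene independently.  Minor allele frequency and CADD deleteriousness
scores are read from configurable INFO keys.  The store replaces a
relational variant database with an in-memory gene index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, NamedTuple, Optional, Sequence, Set

from .errors import AnnotationParseError
from .vcf_io import TrioContext, VariantRecord, record_sort_key

__all__ = [
    "IMPACT_SEVERITY",
    "DEFAULT_EXONIC_TERMS",
    "AnnEntry",
    "AnnotatedVariant",
    "VariantStore",
    "parse_ann_field",
    "build_store",
    "query_gene",
]

#: Severity order for putative impact classes (SnpEff MODERATE is mapped to
#: MED on parse).  Unknown classes rank with MODIFIER.
IMPACT_SEVERITY = {"HIGH": 3, "MED": 2, "LOW": 1, "MODIFIER": 0}

#: Annotation terms counted as exonic by default (coding-sequence changes).
DEFAULT_EXONIC_TERMS = frozenset({
    "missense_variant",
    "synonymous_variant",
    "stop_gained",
    "stop_lost",
    "start_lost",
    "frameshift_variant",
    "inframe_insertion",
    "inframe_deletion",
    "disruptive_inframe_insertion",
    "disruptive_inframe_deletion",
})


class AnnEntry(NamedTuple):
    allele: str
    annotation_term: str
    impact: str
    gene: str


def parse_ann_field(ann_value: str) -> List[AnnEntry]:
    """Parse an ANN INFO value: comma-separated entries, pipe-delimited
    fields at the standard positions (allele | annotation | impact | gene).
    SnpEff's MODERATE impact class is mapped to MED."""
    entries = []
    for chunk in str(ann_value).split(","):
        fields = chunk.split("|")
        if len(fields) < 4:
            raise AnnotationParseError(
                f"ANN entry needs >= 4 pipe-delimited fields, got {len(fields)}: {chunk!r}")
        impact = fields[2].strip()
        if impact == "MODERATE":
            impact = "MED"
        entries.append(AnnEntry(fields[0].strip(), fields[1].strip(), impact,
                                fields[3].strip()))
    return entries


@dataclass(frozen=True)
class AnnotatedVariant:
    """A variant joined to one gene's annotation summary."""

    record: VariantRecord
    gene: str
    impact: str
    exonic: bool
    maf: Optional[float]
    cadd: Optional[float]
    annotation_term: str

    @property
    def chrom(self) -> str:
        return self.record.chrom

    @property
    def pos(self) -> int:
        return self.record.pos


@dataclass
class VariantStore:
    """Gene-indexed collection of annotated variants."""

    variants: List[AnnotatedVariant] = field(default_factory=list)
    by_gene: Dict[str, List[AnnotatedVariant]] = field(default_factory=dict)
    trio: Optional[TrioContext] = None

    def rebuild_index(self) -> Dict[str, List[AnnotatedVariant]]:
        index: Dict[str, List[AnnotatedVariant]] = {}
        for v in self.variants:
            index.setdefault(v.gene, []).append(v)
        for vs in index.values():
            vs.sort(key=lambda v: record_sort_key(v.record))
        return index

    def genes(self) -> List[str]:
        return sorted(self.by_gene)


def _float_or_none(value) -> Optional[float]:
    if value is None or value is True:
        return None
    try:
        return float(value)
    except (TypeError, ValueError):
        return None


def build_store(records: Sequence[VariantRecord],
                trio: Optional[TrioContext] = None,
                maf_key: str = "MAF",
                cadd_key: str = "CADD",
                exonic_terms: Set[str] = DEFAULT_EXONIC_TERMS,
                ann_key: str = "ANN") -> VariantStore:
    """Build the variant store from annotated records.

    Per (record, gene): impact is the most severe among that gene's
    entries; ``exonic`` is true iff any of that gene's terms is in
    ``exonic_terms``; the reported ``annotation_term`` belongs to the most
    severe entry (lexicographic tie-break, so the summary does not depend
    on ANN entry order).  Records without an ANN field contribute no store
    entries; absent MAF/CADD keys yield ``None``.
    """
    store = VariantStore(trio=trio)
    for rec in records:
        ann_value = rec.info.get(ann_key)
        if ann_value in (None, True, ""):
            continue
        entries = parse_ann_field(ann_value)
        maf = _float_or_none(rec.info.get(maf_key))
        cadd = _float_or_none(rec.info.get(cadd_key))
        per_gene: Dict[str, List[AnnEntry]] = {}
        for e in entries:
            per_gene.setdefault(e.gene, []).append(e)
        for gene, gene_entries in per_gene.items():
            best = min(
                gene_entries,
                key=lambda e: (-IMPACT_SEVERITY.get(e.impact, 0), e.annotation_term),
            )
            store.variants.append(AnnotatedVariant(
                record=rec,
                gene=gene,
                impact=best.impact,
                exonic=any(e.annotation_term in exonic_terms for e in gene_entries),
                maf=maf,
                cadd=cadd,
                annotation_term=best.annotation_term,
            ))
    store.by_gene = store.rebuild_index()
    return store


def query_gene(store: VariantStore, gene: str) -> List[AnnotatedVariant]:
    """All annotated variants for a gene, position-sorted; [] when unknown."""
    return list(store.by_gene.get(gene, []))


def export_store_tsv(store: VariantStore, path):
    """Dump the store as a TSV for inspection."""
    from pathlib import Path
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("gene\tchrom\tpos\tref\talt\timpact\texonic\tmaf\tcadd\tannotation_term\n")
        for gene in store.genes():
            for v in store.by_gene[gene]:
                alt = v.record.alts[0] if v.record.alts else "."
                fh.write("\t".join([
                    gene, v.chrom, str(v.pos), v.record.ref, alt, v.impact,
                    "1" if v.exonic else "0",
                    "." if v.maf is None else repr(v.maf),
                    "." if v.cadd is None else repr(v.cadd),
                    v.annotation_term,
                ]) + "\n")
    return path
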