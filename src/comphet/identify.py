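"""Candidate identification: compound-het pairs, homozygous-alternate and
de novo variants, with Gene Damage Index annotation.

A compound-heterozygous (CH) candidate is a pair of heterozygous variants
at distinct positions in the same gene whose alternate alleles lie on
opposite parental haplotypes (trans): one paternal-alt (1|0) and one
maternal-alt (0|1).  Both members must pass the rarity/deleteriousness
filters.  Unphased or ambiguous heterozygotes never enter pairing — trans
configuration is unverifiable without phase — and a count of such
exclusions is kept.

Filters are conjunctive: MAF <= maf_max, CADD >= cadd_min, exonic
classification (when required), and HIGH or MED putative impact.  Missing
MAF or CADD fails the filter (fail-closed).

GDI annotation joins per-gene Gene Damage Index scores and gene lengths;
genes at or below the damage threshold (default 13.84) are classified as
more likely to harbour disease-causing damage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from .annotate_query import AnnotatedVariant, VariantStore, query_gene
from .errors import ModeError, TableParseError
from .vcf_io import Genotype, record_sort_key

__all__ = [
    "FilterThresholds",
    "GDIRecord",
    "CandidateReport",
    "passes_filters",
    "find_compound_het",
    "find_hom_alt",
    "find_de_novo",
    "annotate_gdi",
    "load_gdi_table",
    "load_length_table",
    "write_reports",
    "GDI_DAMAGE_THRESHOLD",
]

logger = logging.getLogger(__name__)

#: Published Gene Damage Index cut-off: scores <= 13.84 mark genes more
#: likely to carry disease-causing damage.
GDI_DAMAGE_THRESHOLD = 13.84


@dataclass(frozen=True)
class FilterThresholds:
    """Conjunctive inclusion filters for candidate variants."""

    maf_max: float = 0.01
    cadd_min: float = 15.0
    allowed_impacts: frozenset = frozenset({"HIGH", "MED"})
    require_exonic: bool = True

    def __post_init__(self):
        if not 0.0 <= self.maf_max <= 1.0:
            raise ValueError(f"maf_max must be in [0, 1], got {self.maf_max}")
        if self.cadd_min < 0:
            raise ValueError(f"cadd_min must be >= 0, got {self.cadd_min}")
        if not self.allowed_impacts:
            raise ValueError("allowed_impacts must be nonempty")
        object.__setattr__(self, "allowed_impacts", frozenset(self.allowed_impacts))


@dataclass(frozen=True)
class GDIRecord:
    gene: str
    gdi_score: float
    gene_length: Optional[int]
    damage_class: str  # "likely" | "unlikely"


@dataclass(frozen=True)
class CandidateReport:
    """One identified candidate: a CH pair (two variants) or a single
    hom-alt / de novo variant, with per-variant inheritance side."""

    kind: str  # "compound_het" | "hom_alt" | "de_novo"
    gene: str
    variants: Tuple[AnnotatedVariant, ...]
    inheritance: Tuple[str, ...]  # per-variant: paternal | maternal | undetermined
    gdi: Optional[GDIRecord] = None

    def __post_init__(self):
        if self.kind == "compound_het":
            if len(self.variants) != 2:
                raise ValueError("compound_het reports carry exactly 2 variants")
            if self.variants[0].pos == self.variants[1].pos \
                    and self.variants[0].chrom == self.variants[1].chrom:
                raise ValueError("compound_het variants must be at distinct positions")
            if set(self.inheritance) != {"paternal", "maternal"}:
                raise ValueError("compound_het inheritance sides must differ")
        elif len(self.variants) != 1:
            raise ValueError(f"{self.kind} reports carry exactly 1 variant")


def passes_filters(v: AnnotatedVariant, t: FilterThresholds) -> bool:
    """MAF <= maf_max AND CADD >= cadd_min AND exonic (when required) AND
    impact allowed; missing MAF or CADD fails (fail-closed)."""
    if v.maf is None or v.cadd is None:
        return False
    if v.maf > t.maf_max or v.cadd < t.cadd_min:
        return False
    if t.require_exonic and not v.exonic:
        return False
    return v.impact in t.allowed_impacts


def _child_gt(v: AnnotatedVariant, store: VariantStore) -> Genotype:
    return v.record.genotypes[store.trio.child_id]


def _parent_gt(v: AnnotatedVariant, store: VariantStore, which: str) -> Genotype:
    sid = store.trio.father_id if which == "father" else store.trio.mother_id
    return v.record.genotypes.get(sid, Genotype(None, None))


def find_compound_het(store: VariantStore, t: FilterThresholds) -> List[CandidateReport]:
    """All trans-configured filter-passing het pairs, per gene.

    Requires a trio-built store.  Output order is deterministic
    (gene, then positions) and independent of input record order.
    """
    if store.trio is None:
        raise ModeError("compound-het identification requires a trio")
    reports: List[CandidateReport] = []
    n_unphased_het = 0
    for gene in store.genes():
        paternal: List[AnnotatedVariant] = []
        maternal: List[AnnotatedVariant] = []
        for v in query_gene(store, gene):
            if not passes_filters(v, t):
                continue
            gt = _child_gt(v, store)
            if not gt.is_het or None in gt.alleles:
                continue
            if not gt.phased:
                n_unphased_het += 1
                continue
            if gt.alleles == (1, 0):
                paternal.append(v)
            elif gt.alleles == (0, 1):
                maternal.append(v)
        for vp in paternal:
            for vm in maternal:
                if (vp.chrom, vp.pos) == (vm.chrom, vm.pos):
                    continue
                pair = sorted((vp, vm), key=lambda v: record_sort_key(v.record))
                sides = tuple(
                    "paternal" if v.record.genotypes[store.trio.child_id].alleles == (1, 0)
                    else "maternal"
                    for v in pair
                )
                reports.append(CandidateReport(
                    kind="compound_het", gene=gene,
                    variants=tuple(pair), inheritance=sides,
                ))
    if n_unphased_het:
        logger.info("compound-het pairing skipped %d unphased/ambiguous heterozygotes",
                    n_unphased_het)
    reports.sort(key=lambda r: (r.gene, record_sort_key(r.variants[0].record),
                                record_sort_key(r.variants[1].record)))
    return reports


def find_hom_alt(store: VariantStore, t: FilterThresholds,
                 require_carrier_parents: bool = False) -> List[CandidateReport]:
    """Filter-passing variants with a homozygous-alternate child genotype.

    ``require_carrier_parents`` adds a strict recessive-model check: both
    parents must carry at least one alternate allele.
    """
    reports = []
    for gene in store.genes():
        for v in query_gene(store, gene):
            if not passes_filters(v, t):
                continue
            gt = v.record.genotypes.get(store.trio.child_id) if store.trio \
                else _sole_genotype(v)
            if gt is None or gt.alleles != (1, 1):
                continue
            if require_carrier_parents:
                if store.trio is None:
                    raise ModeError("carrier-parent check requires a trio")
                if _parent_gt(v, store, "father").alt_count < 1 \
                        or _parent_gt(v, store, "mother").alt_count < 1:
                    continue
            reports.append(CandidateReport(kind="hom_alt", gene=gene,
                                           variants=(v,),
                                           inheritance=("undetermined",)))
    reports.sort(key=lambda r: (r.gene, record_sort_key(r.variants[0].record)))
    return reports


def _sole_genotype(v: AnnotatedVariant) -> Optional[Genotype]:
    gts = list(v.record.genotypes.values())
    return gts[0] if len(gts) == 1 else None


def find_de_novo(store: VariantStore, t: FilterThresholds) -> List[CandidateReport]:
    """Filter-passing variants carried once by the child and absent from
    both parents.  Both parents must be explicitly called homozygous
    reference — a missing parent cannot certify allele absence."""
    if store.trio is None:
        raise ModeError("de novo identification requires a trio")
    reports = []
    for gene in store.genes():
        for v in query_gene(store, gene):
            if not passes_filters(v, t):
                continue
            child = _child_gt(v, store)
            if child.sorted_alleles() != (0, 1):
                continue
            if _parent_gt(v, store, "father").alleles != (0, 0):
                continue
            if _parent_gt(v, store, "mother").alleles != (0, 0):
                continue
            reports.append(CandidateReport(kind="de_novo", gene=gene,
                                           variants=(v,),
                                           inheritance=("undetermined",)))
    reports.sort(key=lambda r: (r.gene, record_sort_key(r.variants[0].record)))
    return reports


# ---------------------------------------------------------------------------
# GDI / gene length


def load_gdi_table(path) -> Dict[str, float]:
    """TSV gene -> GDI score; one header line tolerated."""
    return {g: float(v) for g, v in _read_two_column_tsv(path)}


def load_length_table(path) -> Dict[str, int]:
    """TSV gene -> gene length in base pairs; one header line tolerated."""
    return {g: int(float(v)) for g, v in _read_two_column_tsv(path)}


def _read_two_column_tsv(path):
    rows = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) < 2:
                raise TableParseError(f"{path} line {lineno}: expected 2 columns")
            if lineno == 1:
                try:
                    float(cols[1])
                except ValueError:
                    continue  # header
            try:
                float(cols[1])
            except ValueError as exc:
                raise TableParseError(
                    f"{path} line {lineno}: non-numeric value {cols[1]!r}") from exc
            rows.append((cols[0].upper(), cols[1]))
    return rows


def annotate_gdi(reports: Sequence[CandidateReport],
                 gdi_table: Mapping[str, float],
                 length_table: Optional[Mapping[str, int]] = None,
                 damage_threshold: float = GDI_DAMAGE_THRESHOLD) -> List[CandidateReport]:
    """Left-join GDI scores and gene lengths onto reports by
    case-insensitive gene symbol; genes absent from the table keep a null
    GDI field (logged)."""
    gdi_upper = {g.upper(): s for g, s in gdi_table.items()}
    len_upper = {g.upper(): l for g, l in (length_table or {}).items()}
    out = []
    for r in reports:
        key = r.gene.upper()
        if key in gdi_upper:
            score = float(gdi_upper[key])
            gdi = GDIRecord(
                gene=r.gene,
                gdi_score=score,
                gene_length=len_upper.get(key),
                damage_class="likely" if score <= damage_threshold else "unlikely",
            )
        else:
            logger.warning("gene %s absent from GDI table", r.gene)
            gdi = None
        out.append(replace(r, gdi=gdi))
    return out


# ---------------------------------------------------------------------------
# report output

_REPORT_COLUMNS = [
    "gene", "chrom", "pos", "ref", "alt", "child_gt", "father_gt", "mother_gt",
    "maf", "cadd", "impact", "annotation_term", "inheritance",
    "gdi_score", "damage_class", "gene_length",
]


def write_reports(reports: Sequence[CandidateReport], store: VariantStore, path):
    """Write one TSV row per reported variant (CH pairs contribute two rows
    sharing a trailing pair_id)."""
    from pathlib import Path
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with_pairs = any(r.kind == "compound_het" for r in reports)
    cols = _REPORT_COLUMNS + (["pair_id"] if with_pairs else [])
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("\t".join(cols) + "\n")
        for idx, r in enumerate(reports):
            for v, side in zip(r.variants, r.inheritance):
                rec = v.record
                if store.trio is not None:
                    child = rec.genotypes.get(store.trio.child_id)
                    father = rec.genotypes.get(store.trio.father_id)
                    mother = rec.genotypes.get(store.trio.mother_id)
                else:
                    child, father, mother = _sole_genotype(v), None, None
                row = [
                    r.gene, v.chrom, str(v.pos), rec.ref,
                    rec.alts[0] if rec.alts else ".",
                    child.token() if child else ".",
                    father.token() if father else ".",
                    mother.token() if mother else ".",
                    "." if v.maf is None else f"{v.maf:g}",
                    "." if v.cadd is None else f"{v.cadd:g}",
                    v.impact, v.annotation_term, side,
                    f"{r.gdi.gdi_score:g}" if r.gdi else ".",
                    r.gdi.damage_class if r.gdi else ".",
                    str(r.gdi.gene_length) if r.gdi and r.gdi.gene_length is not None else ".",
                ]
                if with_pairs:
                    row.append(str(idx) if r.kind == "compound_het" else ".")
                fh.write("\t".join(row) + "\n")
    return path
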