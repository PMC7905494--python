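"""Mendelian trio phasing, Mendelian-error detection and REF/ALT repair.

At a biallelic site the child receives exactly one allele from each parent.
Enumerating every (paternal transmission, maternal transmission) pair that
reproduces the child's genotype gives four mutually exclusive outcomes:

* exactly one consistent ordered pair  -> the site is *phased* (the child
  genotype is written paternal|maternal);
* more than one                        -> *ambiguous* (classically: all three
  trio members heterozygous), left unphased;
* none, with the child carrying a single alternate allele and both parents
  called homozygous reference          -> *potential de novo* — retained so
  de novo identification downstream remains possible;
* none otherwise                       -> *Mendelian error*, removed.

A fully or partially missing parental allele constrains nothing (wildcard).
Statistical panel-based phasing of ambiguous sites is deliberately out of
scope; ambiguous sites are flagged and never enter compound-het pairing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from .errors import (ConcatenationError, ContractViolationError, CoordinateError)
from .vcf_io import (Genotype, MISSING, TrioContext, VariantRecord,
                     record_sort_key)

__all__ = [
    "PhaseStatus",
    "PhaseResult",
    "split_by_chromosome",
    "mendelian_phase_site",
    "detect_mendelian_error",
    "fix_ref_alt_congruence",
    "phase_records",
    "concatenate_chromosomes",
    "PHASE_STATUS_KEY",
]

#: INFO key used to flag ambiguous / potential-de-novo sites in output VCFs.
PHASE_STATUS_KEY = "PSTAT"


class PhaseStatus:
    PHASED = "phased"
    AMBIGUOUS = "ambiguous"
    MENDELIAN_ERROR = "mendelian_error"
    POTENTIAL_DE_NOVO = "potential_de_novo"
    INCONGRUENT = "incongruent"


@dataclass(frozen=True)
class PhaseResult:
    """Outcome of Mendelian phasing at one site.

    ``child_phased`` is ordered paternal|maternal when status is ``phased``.
    Parental phased genotypes are ordered transmitted-allele-first and are
    only reported when the parent is fully called.
    """

    status: str
    child_phased: Optional[Genotype] = None
    father_phased: Optional[Genotype] = None
    mother_phased: Optional[Genotype] = None


def _check_biallelic(gt: Genotype, who: str):
    for a in gt.alleles:
        if a is not None and a not in (0, 1):
            raise ContractViolationError(
                f"{who} genotype {gt.token()} has allele index {a} at a biallelic-only step")


def _transmissible(gt: Genotype) -> frozenset:
    """Alleles a parent can transmit; a missing allele is a wildcard."""
    out = set()
    for a in gt.alleles:
        out.update((0, 1) if a is None else (a,))
    return frozenset(out)


def _child_matches(child: Genotype, p: int, m: int) -> bool:
    """Does transmission (paternal=p, maternal=m) reproduce the child's
    allele multiset?  A missing child allele matches anything."""
    ca, cb = child.alleles
    for x, y in ((ca, cb), (cb, ca)):
        if (x is None or x == p) and (y is None or y == m):
            return True
    return False


def consistent_transmissions(child: Genotype, father: Genotype,
                             mother: Genotype) -> List[Tuple[int, int]]:
    """All ordered (paternal, maternal) transmissions consistent with the
    trio's genotypes, missing alleles acting as wildcards."""
    for gt, who in ((child, "child"), (father, "father"), (mother, "mother")):
        _check_biallelic(gt, who)
    return [
        (p, m)
        for p in sorted(_transmissible(father))
        for m in sorted(_transmissible(mother))
        if _child_matches(child, p, m)
    ]


def _is_hom_ref_called(gt: Genotype) -> bool:
    return gt.alleles == (0, 0)


def mendelian_phase_site(child: Genotype, father: Genotype,
                         mother: Genotype) -> PhaseResult:
    """Phase one biallelic site by transmission logic (see module docstring)."""
    if _is_hom_ref_called(father) and _is_hom_ref_called(mother) \
            and child.sorted_alleles() == (0, 1):
        return PhaseResult(status=PhaseStatus.POTENTIAL_DE_NOVO)
    options = consistent_transmissions(child, father, mother)
    if not options:
        return PhaseResult(status=PhaseStatus.MENDELIAN_ERROR)
    if child.has_missing:
        # an uncalled child allele cannot be assigned to a haplotype
        return PhaseResult(status=PhaseStatus.AMBIGUOUS)
    if len(options) > 1:
        return PhaseResult(status=PhaseStatus.AMBIGUOUS)
    p, m = options[0]
    return PhaseResult(
        status=PhaseStatus.PHASED,
        child_phased=Genotype(p, m, phased=True),
        father_phased=_parent_phased(father, p),
        mother_phased=_parent_phased(mother, m),
    )


def _parent_phased(parent: Genotype, transmitted: int) -> Optional[Genotype]:
    if parent.has_missing:
        return None
    a, b = parent.alleles
    if transmitted == a:
        return Genotype(transmitted, b, phased=True)
    if transmitted == b:
        return Genotype(transmitted, a, phased=True)
    return None


def detect_mendelian_error(child: Genotype, father: Genotype,
                           mother: Genotype) -> bool:
    """True iff no choice of one allele from each parent reproduces the
    child's allele multiset (missing alleles are wildcards)."""
    return not consistent_transmissions(child, father, mother)


# ---------------------------------------------------------------------------
# chromosome split / concatenate


def split_by_chromosome(records: Sequence[VariantRecord]) -> Dict[str, List[VariantRecord]]:
    """Partition sorted records by contig, preserving order."""
    out: Dict[str, List[VariantRecord]] = {}
    for r in records:
        out.setdefault(r.chrom, []).append(r)
    return out


def concatenate_chromosomes(per_contig: Mapping[str, Sequence[VariantRecord]]) -> List[VariantRecord]:
    """Inverse of :func:`split_by_chromosome`: one sorted record set."""
    for contig, records in per_contig.items():
        for r in records:
            if r.chrom != contig:
                raise ConcatenationError(
                    f"record at {r.chrom}:{r.pos} filed under contig {contig!r}")
    merged = [r for records in per_contig.values() for r in records]
    merged.sort(key=record_sort_key)
    return merged


# ---------------------------------------------------------------------------
# REF/ALT congruence repair


def fix_ref_alt_congruence(record: VariantRecord,
                           reference: Mapping[str, str]) -> Optional[VariantRecord]:
    """Repair a record whose REF/ALT were swapped relative to the reference.

    Returns the record unchanged when REF matches the reference sequence at
    its locus; returns a swapped record (REF<->ALT, genotype indices
    inverted 0<->1, phase order preserved) when only the single ALT matches;
    returns ``None`` (site removed, reason ``incongruent``) when neither
    matches.
    """
    try:
        seq = reference[record.chrom]
    except KeyError as exc:
        raise CoordinateError(f"contig {record.chrom!r} absent from reference") from exc
    if record.pos + len(record.ref) - 1 > len(seq):
        raise CoordinateError(
            f"{record.chrom}:{record.pos} + ref length exceeds contig end ({len(seq)})")
    window = str(seq[record.pos - 1: record.pos - 1 + len(record.ref)]).upper()
    if window == record.ref.upper():
        return record
    if len(record.alts) == 1:
        alt = record.alts[0]
        if record.pos + len(alt) - 1 <= len(seq):
            alt_window = str(seq[record.pos - 1: record.pos - 1 + len(alt)]).upper()
            if alt_window == alt.upper():
                swapped_gts = {
                    s: Genotype(_invert(g.allele_a), _invert(g.allele_b), g.phased)
                    for s, g in record.genotypes.items()
                }
                return record.replace(ref=alt, alts=(record.ref,), genotypes=swapped_gts)
    return None


def _invert(a: Optional[int]) -> Optional[int]:
    if a is None:
        return None
    return 1 - a


# ---------------------------------------------------------------------------
# per-record-set phasing


def phase_records(records: Sequence[VariantRecord], trio: TrioContext,
                  reference: Mapping[str, str]):
    """Apply congruence repair then Mendelian phasing to every site.

    Congruence repair runs first: a swapped site would otherwise be falsely
    flagged as a Mendelian error.  Mendelian-error sites are removed;
    ambiguous and potential-de-novo sites are retained unphased and flagged
    via the ``PSTAT`` INFO key.

    Returns ``(phased_records, site_log)`` with one ``(chrom, pos, status)``
    log entry per input record.
    """
    out: List[VariantRecord] = []
    log: List[Tuple[str, int, str]] = []
    for rec in records:
        fixed = fix_ref_alt_congruence(rec, reference)
        if fixed is None:
            log.append((rec.chrom, rec.pos, PhaseStatus.INCONGRUENT))
            continue
        child = fixed.genotypes.get(trio.child_id, Genotype(MISSING, MISSING))
        father = fixed.genotypes.get(trio.father_id, Genotype(MISSING, MISSING))
        mother = fixed.genotypes.get(trio.mother_id, Genotype(MISSING, MISSING))
        result = mendelian_phase_site(child, father, mother)
        log.append((fixed.chrom, fixed.pos, result.status))
        if result.status == PhaseStatus.MENDELIAN_ERROR:
            continue
        genotypes = dict(fixed.genotypes)
        info = dict(fixed.info)
        if result.status == PhaseStatus.PHASED:
            genotypes[trio.child_id] = result.child_phased
            if result.father_phased is not None:
                genotypes[trio.father_id] = result.father_phased
            if result.mother_phased is not None:
                genotypes[trio.mother_id] = result.mother_phased
        elif result.status == PhaseStatus.AMBIGUOUS:
            info[PHASE_STATUS_KEY] = "ambiguous"
        elif result.status == PhaseStatus.POTENTIAL_DE_NOVO:
            info[PHASE_STATUS_KEY] = "denovo"
        out.append(fixed.replace(info=info, genotypes=genotypes))
    return out, log


def write_site_log(log: Iterable[Tuple[str, int, str]], path):
    from pathlib import Path
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("chrom\tpos\tstatus\n")
        for chrom, pos, status in log:
            fh.write(f"{chrom}\t{pos}\t{status}\n")
    return path
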