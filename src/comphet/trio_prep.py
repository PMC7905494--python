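"""Trio harmonization, merging and site-hygiene filtering.

Three single-sample call sets (child, father, mother) are reduced to the
child's variant sites, merged into one multi-sample record set, and cleaned
of multiallelic sites, duplicated positions, and sites where both parents
are fully missing — the site classes that break downstream phasing.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from collections import Counter, defaultdict
from typing import Iterable, List, Optional, Sequence, Tuple

from .errors import HarmonizationError, MergeConflictError
from .vcf_io import (Genotype, MISSING, TrioContext, VariantRecord,
                     contig_sort_key, record_sort_key)

__all__ = ["harmonize_trio", "combine_trio", "filter_sites", "REMOVAL_REASONS"]

REMOVAL_REASONS = ("multiallelic", "duplicate", "parents_missing")


def harmonize_trio(child_records: Sequence[VariantRecord],
                   father_records: Sequence[VariantRecord],
                   mother_records: Sequence[VariantRecord],
                   mode: str = "vcf"):
    """Restrict parental records to the child's variant positions.

    The child's gVCF non-variant blocks are dropped.  A parental gVCF block
    overlapping a retained child site is collapsed to an explicit homozygous
    reference genotype at that site (using the child's alleles), since block
    coverage certifies 0/0 there.  Matching is by (contig, position) only;
    allele conflicts surface later at merge time.

    Returns ``(child_out, father_out, mother_out)``.
    """
    if not child_records:
        raise HarmonizationError("child record set is empty")
    child_out = [r for r in child_records if not r.is_non_variant]
    if not child_out:
        raise HarmonizationError("child record set contains no variant sites")

    child_by_key = {}
    for r in child_out:
        child_by_key.setdefault(r.key, r)
    # per-contig sorted child positions, for block interval queries
    child_pos = defaultdict(list)
    for r in child_out:
        child_pos[r.chrom].append(r.pos)
    for positions in child_pos.values():
        positions.sort()

    def one_parent(records: Sequence[VariantRecord]) -> List[VariantRecord]:
        direct = {}
        synthesized = {}
        for r in records:
            if r.is_non_variant:
                if mode != "gvcf":
                    continue
                positions = child_pos.get(r.chrom, [])
                lo = bisect_left(positions, r.pos)
                hi = bisect_right(positions, r.end)
                for p in positions[lo:hi]:
                    key = (r.chrom, p)
                    template = child_by_key[key]
                    sample = next(iter(r.genotypes), None)
                    gts = {sample: Genotype(0, 0)} if sample else {}
                    synthesized[key] = template.replace(
                        id=None, qual=None, filter=".", info={}, genotypes=gts,
                    )
            elif r.key in child_by_key:
                direct[r.key] = r
        merged = dict(synthesized)
        merged.update(direct)  # an explicit variant record beats a block
        return sorted(merged.values(), key=record_sort_key)

    return child_out, one_parent(father_records), one_parent(mother_records)


def _reindex(gt: Genotype, alts: Tuple[str, ...], union: List[str]) -> Genotype:
    """Map a member's genotype indices onto the union alt list."""
    def remap(a):
        if a is None or a == 0:
            return a
        return union.index(alts[a - 1]) + 1
    return Genotype(remap(gt.allele_a), remap(gt.allele_b), gt.phased)


def combine_trio(child_records: Sequence[VariantRecord],
                 father_records: Sequence[VariantRecord],
                 mother_records: Sequence[VariantRecord],
                 trio: TrioContext) -> List[VariantRecord]:
    """Merge harmonized per-member record sets into one multi-sample set.

    Sample columns are ordered child, father, mother.  A member with no
    record at a site is fully missing there.  Differing alternate alleles
    produce a merged multiallelic record (removed later by
    :func:`filter_sites`); REF disagreement raises
    :class:`MergeConflictError`.  INFO (annotations) is taken from the
    child's record, the site owner.
    """
    member_sets = (child_records, father_records, mother_records)
    sample_ids = trio.sample_ids
    indexed = []
    for records in member_sets:
        by_key = defaultdict(list)
        for r in records:
            by_key[r.key].append(r)
        indexed.append(by_key)

    keys = sorted({k for idx in indexed for k in idx},
                  key=lambda k: (contig_sort_key(k[0]), k[1]))
    out: List[VariantRecord] = []
    for key in keys:
        lists = [idx.get(key, []) for idx in indexed]
        depth = max(len(l) for l in lists)
        for i in range(depth):
            present = [(sid, l[i]) for sid, l in zip(sample_ids, lists) if i < len(l)]
            refs = {r.ref for _, r in present}
            if len(refs) > 1:
                raise MergeConflictError(
                    f"REF disagreement at {key[0]}:{key[1]}: {sorted(refs)}")
            child_rec = lists[0][i] if i < len(lists[0]) else None
            base = child_rec if child_rec is not None else present[0][1]
            union: List[str] = []
            ordered = ([child_rec] if child_rec is not None else []) + \
                [r for _, r in present if r is not child_rec]
            for r in ordered:
                for alt in r.alts:
                    if alt not in union:
                        union.append(alt)
            genotypes = {}
            for sid, l in zip(sample_ids, lists):
                if i < len(l):
                    rec = l[i]
                    gt = rec.genotypes.get(next(iter(rec.genotypes), sid),
                                           Genotype(MISSING, MISSING))
                    genotypes[sid] = _reindex(gt, rec.alts, union)
                else:
                    genotypes[sid] = Genotype(MISSING, MISSING)
            out.append(base.replace(
                alts=tuple(union),
                info=dict(child_rec.info) if child_rec is not None else {},
                genotypes=genotypes,
            ))
    return out


def filter_sites(records: Sequence[VariantRecord],
                 trio: Optional[TrioContext] = None):
    """Remove multiallelic sites, duplicated positions, and (in trio mode)
    sites where both parents are fully missing.

    Duplicate removal drops *all* records sharing a position.  Half-missing
    parental genotypes (e.g. ``./1``) count as non-missing.  Each removed
    record is logged with exactly one reason, assigned in the precedence
    multiallelic > duplicate > parents_missing.

    Returns ``(kept, removal_log)`` where the log is a list of
    ``(chrom, pos, reason)`` tuples.
    """
    pos_counts = Counter(r.key for r in records)
    kept: List[VariantRecord] = []
    log: List[Tuple[str, int, str]] = []
    for r in records:
        if len(r.alts) > 1:
            log.append((r.chrom, r.pos, "multiallelic"))
        elif pos_counts[r.key] > 1:
            log.append((r.chrom, r.pos, "duplicate"))
        elif trio is not None and _both_parents_missing(r, trio):
            log.append((r.chrom, r.pos, "parents_missing"))
        else:
            kept.append(r)
    return kept, log


def _both_parents_missing(rec: VariantRecord, trio: TrioContext) -> bool:
    father = rec.genotypes.get(trio.father_id, Genotype(MISSING, MISSING))
    mother = rec.genotypes.get(trio.mother_id, Genotype(MISSING, MISSING))
    return father.is_missing and mother.is_missing


def write_removal_log(log: Iterable[Tuple[str, int, str]], path):
    from pathlib import Path
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("chrom\tpos\treason\n")
        for chrom, pos, reason in log:
            fh.write(f"{chrom}\t{pos}\t{reason}\n")
    return path
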