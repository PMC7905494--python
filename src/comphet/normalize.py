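"""Variant normalization: left-alignment and parsimonious trimming.

A variant representation ``(pos, ref, alts)`` is *normalized* when it is
expressed at its left-most reference position with as few nucleotides as
possible.  The canonical algorithm:

(a) while every allele ends with the same base, truncate that base; if any
    allele becomes empty, prepend the reference base at ``pos - 1`` to every
    allele and decrement ``pos``;
(b) while every allele begins with the same base and every allele has
    length >= 2, remove the first base and increment ``pos``.

Normalization never changes the alternate haplotype sequence the variant
encodes — only its textual representation.  Multiallelic sites are handled
jointly (the shared-base conditions quantify over the full allele set).
"""

from __future__ import annotations

from typing import List, Sequence, Tuple

from .errors import NormalizationError

__all__ = ["normalize_variant", "is_normalized", "apply_variant"]


def _check_ref(pos: int, ref: str, contig_seq: str):
    if pos < 1 or pos + len(ref) - 1 > len(contig_seq):
        raise NormalizationError(
            f"locus {pos}..{pos + len(ref) - 1} outside contig of length {len(contig_seq)}")
    window = str(contig_seq[pos - 1: pos - 1 + len(ref)]).upper()
    if window != ref.upper():
        raise NormalizationError(
            f"ref allele {ref!r} does not match reference {window!r} at pos {pos}")


def normalize_variant(pos: int, ref: str, alts: Sequence[str],
                      contig_seq: str) -> Tuple[int, str, Tuple[str, ...]]:
    """Return the left-aligned, trimmed representation of a variant.

    Raises :class:`NormalizationError` when ``ref`` does not match the
    reference at ``pos`` or when left extension is required at position 1
    (no context base exists).
    """
    if not alts or any(not a for a in alts):
        raise NormalizationError("alleles must be non-empty")
    _check_ref(pos, ref, contig_seq)
    alleles: List[str] = [ref.upper(), *(a.upper() for a in alts)]
    seq = str(contig_seq).upper()

    changed = True
    while changed:
        changed = False
        # (a) shared trailing base: truncate; extend left if something empties
        while len({a[-1] for a in alleles}) == 1:
            alleles = [a[:-1] for a in alleles]
            changed = True
            if any(not a for a in alleles):
                if pos == 1:
                    raise NormalizationError(
                        "left extension required at contig start (pos=1)")
                pos -= 1
                base = seq[pos - 1]
                alleles = [base + a for a in alleles]
        # (b) shared leading base with all lengths >= 2: trim left
        while len({a[0] for a in alleles}) == 1 and all(len(a) >= 2 for a in alleles):
            alleles = [a[1:] for a in alleles]
            pos += 1
            changed = True
    return pos, alleles[0], tuple(alleles[1:])


def is_normalized(pos: int, ref: str, alts: Sequence[str], contig_seq: str) -> bool:
    """True iff the representation is already left-aligned and trimmed:
    the alleles do not all share an end base, and do not all share a start
    base while all having length >= 2."""
    _check_ref(pos, ref, contig_seq)
    alleles = [ref.upper(), *(a.upper() for a in alts)]
    if len({a[-1] for a in alleles}) == 1:
        return False
    if len({a[0] for a in alleles}) == 1 and all(len(a) >= 2 for a in alleles):
        return False
    return True


def apply_variant(contig_seq: str, pos: int, ref: str, alt: str) -> str:
    """The alternate haplotype sequence a (pos, ref, alt) substitution
    encodes; used to verify that normalization preserves meaning."""
    _check_ref(pos, ref, contig_seq)
    seq = str(contig_seq).upper()
    return seq[: pos - 1] + alt.upper() + seq[pos - 1 + len(ref):]
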