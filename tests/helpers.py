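"""Independent oracles shared across tests.

These deliberately re-derive expected behaviour by brute force — exhaustive
enumeration of wildcard substitutions for trio transmission, and exhaustive
candidate search over the contig for variant normalization — so they share
no code path with the implementation they check.
"""

from collections import Counter
from itertools import product

from comphet.vcf_io import Genotype


# ---------------------------------------------------------------------------
# Mendelian transmission oracle


def _expand(gt):
    """All concrete biallelic genotypes compatible with a possibly-missing
    genotype (each missing allele replaced by 0 and by 1)."""
    slots = [(a,) if a is not None else (0, 1) for a in gt.alleles]
    return [tuple(c) for c in product(*slots)]


def oracle_transmissions(child: Genotype, father: Genotype, mother: Genotype):
    """Distinct ordered (paternal, maternal) transmissions reproducing the
    child's allele multiset under every wildcard substitution."""
    found = set()
    for c, f, m in product(_expand(child), _expand(father), _expand(mother)):
        for p in set(f):
            for q in set(m):
                if Counter((p, q)) == Counter(c):
                    found.add((p, q))
    return found


def oracle_status(child: Genotype, father: Genotype, mother: Genotype) -> str:
    """Classify a trio genotype combination the way the phaser must:
    de novo beats error; error = zero consistent transmissions; phased =
    exactly one with a fully-called child; otherwise ambiguous."""
    if father.alleles == (0, 0) and mother.alleles == (0, 0) \
            and sorted(child.alleles, key=lambda a: (a is None, a)) == [0, 1]:
        return "potential_de_novo"
    options = oracle_transmissions(child, father, mother)
    if not options:
        return "mendelian_error"
    if child.has_missing:
        return "ambiguous"
    return "phased" if len(options) == 1 else "ambiguous"


def all_trio_genotypes(include_missing=True):
    """Every (child, father, mother) combination of biallelic genotypes;
    with ``include_missing`` the allele alphabet also contains '.'."""
    alleles = (0, 1, None) if include_missing else (0, 1)
    gts = []
    seen = set()
    for a, b in product(alleles, repeat=2):
        key = tuple(sorted((a, b), key=lambda x: (x is None, x)))
        if key not in seen:
            seen.add(key)
            gts.append(Genotype(a, b))
    return list(product(gts, repeat=3))


# ---------------------------------------------------------------------------
# Normalization oracle


def oracle_normalize(pos: int, ref: str, alt: str, contig: str):
    """Exhaustive left-most/shortest search: every (pos', ref', alt') whose
    substitution into the contig yields the same alternate sequence; keep
    the shortest total representation, left-most on ties."""
    contig = contig.upper()
    target = contig[: pos - 1] + alt.upper() + contig[pos - 1 + len(ref):]
    n, t = len(contig), len(target)
    best = None
    for p in range(1, n + 1):
        if contig[: p - 1] != target[: p - 1]:
            break
        for rlen in range(1, n - p + 2):
            alen = t - (n - rlen)
            if alen < 1:
                continue
            cand_ref = contig[p - 1: p - 1 + rlen]
            cand_alt = target[p - 1: p - 1 + alen]
            if contig[: p - 1] + cand_alt + contig[p - 1 + rlen:] == target:
                cand = (rlen + alen, p, cand_ref, cand_alt)
                if best is None or cand[:2] < best[:2]:
                    best = cand
    assert best is not None
    return best[1], best[2], best[3]


def random_denormalized_variant(rng, contig: str):
    """A random SNV/insertion/deletion over the contig, optionally rewritten
    with shared flanking bases so it needs trimming and/or left-alignment."""
    n = len(contig)
    kind = rng.choice(["snv", "del", "ins"])
    if kind == "snv":
        pos = int(rng.integers(1, n + 1))
        ref = contig[pos - 1]
        alt = rng.choice([b for b in "ACGT" if b != ref])
    elif kind == "del":
        dlen = int(rng.integers(1, 4))
        pos = int(rng.integers(1, n - dlen))
        ref = contig[pos - 1: pos + dlen]
        alt = ref[0]
    else:
        pos = int(rng.integers(1, n))
        ref = contig[pos - 1]
        alt = ref + "".join(rng.choice(list("ACGT"), size=int(rng.integers(1, 4))))
    # denormalize: append shared reference suffix and/or prepend context base
    end = pos + len(ref) - 1
    for _ in range(int(rng.integers(0, 3))):
        if end < n:
            ref, alt, end = ref + contig[end], alt + contig[end], end + 1
    for _ in range(int(rng.integers(0, 2))):
        if pos > 1:
            pos -= 1
            ref, alt = contig[pos - 1] + ref, contig[pos - 1] + alt
    return pos, ref, alt


def random_repeat_contig(rng, length=50):
    seq = list(rng.choice(list("ACGT"), size=length))
    for _ in range(3):
        unit_len = int(rng.integers(1, 3))
        reps = int(rng.integers(3, 6))
        start = int(rng.integers(0, max(1, length - unit_len * reps)))
        unit = list(rng.choice(list("ACGT"), size=unit_len))
        seq[start: start + unit_len * reps] = unit * reps
    return "".join(seq[:length])
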