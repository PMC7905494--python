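"""Deterministic synthetic trios for exercising every pipeline stage.

The generator emulates a small exome-like study: a reference contig pair
with tandem-repeat tracts (so left-alignment has work to do), per-member
trio VCFs (or gVCFs with <NON_REF> reference blocks), a PED file, toy
SnpEff-style ANN / MAF / CADD annotations, GDI and gene-length tables, and
a truth table listing every planted site with its category and expected
outcome.  Genotypes are Mendelian-consistent by construction except at
sites explicitly planted as Mendelian errors or de novo events.

Same seed, same spec => byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np

from .errors import PlanError
from .normalize import normalize_variant
from .vcf_io import (Genotype, NON_REF_ALT, TrioContext, VariantRecord,
                     record_sort_key, write_vcf)

__all__ = [
    "CATEGORIES",
    "PlantedGene",
    "FixtureSpec",
    "default_plan",
    "generate_reference",
    "generate_trio",
    "simulate",
    "read_truth",
]

CATEGORIES = (
    "trans_pair", "cis_pair", "hom_alt", "de_novo", "mendelian_error",
    "ambiguous", "multiallelic", "duplicate", "parents_missing",
)

_FAIL_MODES = ("maf", "cadd", "exonic", "impact")

_BASES = np.array(list("ACGT"))

CHILD, FATHER, MOTHER = "CHILD", "FATHER", "MOTHER"

TRIO = TrioContext(child_id=CHILD, father_id=FATHER, mother_id=MOTHER)


@dataclass(frozen=True)
class PlantedGene:
    gene: str
    category: str
    filter_fail: Optional[str] = None  # None | maf | cadd | exonic | impact

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise PlanError(f"unknown category {self.category!r}")
        if self.filter_fail is not None and self.filter_fail not in _FAIL_MODES:
            raise PlanError(f"unknown filter-fail mode {self.filter_fail!r}")


def default_plan(n_genes: int) -> List[PlantedGene]:
    """Cycle through every category; on every second full cycle the
    reportable categories (trans_pair, hom_alt, de_novo) are planted with a
    filter-failing member so that negative filtering is exercised too."""
    plan = []
    fail_cycle = 0
    for i in range(n_genes):
        cat = CATEGORIES[i % len(CATEGORIES)]
        fail = None
        if (i // len(CATEGORIES)) % 2 == 1 and cat in ("trans_pair", "hom_alt", "de_novo"):
            fail = _FAIL_MODES[fail_cycle % len(_FAIL_MODES)]
            fail_cycle += 1
        plan.append(PlantedGene(gene=f"GENE{i + 1:03d}", category=cat, filter_fail=fail))
    return plan


@dataclass
class FixtureSpec:
    """Study conditions for one synthetic trio."""

    seed: int = 0
    n_genes: int = 24
    n_sites_per_gene: int = 4
    maf_range: Tuple[float, float] = (1e-4, 5e-3)    # below the 0.01 rarity bound
    cadd_range: Tuple[float, float] = (16.0, 35.0)   # above the 15 deleteriousness bound
    repeat_fraction: float = 0.25
    gene_span: int = 240
    margin: int = 60
    planted: Optional[List[PlantedGene]] = None

    def plan(self) -> List[PlantedGene]:
        plan = self.planted if self.planted is not None else default_plan(self.n_genes)
        if self.n_sites_per_gene < 2:
            for pg in plan:
                if pg.category in ("trans_pair", "cis_pair"):
                    raise PlanError(
                        f"{pg.category} in gene {pg.gene} needs >= 2 sites per gene")
        return plan


# ---------------------------------------------------------------------------
# reference


def _gene_layout(spec: FixtureSpec):
    """Gene -> (contig, start, end); genes split across two contigs."""
    plan = spec.plan()
    half = (len(plan) + 1) // 2
    layout = {}
    for i, pg in enumerate(plan):
        contig = "1" if i < half else "2"
        j = i if i < half else i - half
        start = spec.margin + j * spec.gene_span + 1
        layout[pg.gene] = (contig, start, start + spec.gene_span - 1)
    return layout


def generate_reference(spec: FixtureSpec) -> Dict[str, str]:
    """Random A/C/G/T contigs with ``repeat_fraction`` of bases rewritten as
    >= 3-unit tandem repeats (units of 1-3 bp)."""
    rng = np.random.default_rng(spec.seed)
    layout = _gene_layout(spec)
    lengths = {}
    for contig, start, end in layout.values():
        lengths[contig] = max(lengths.get(contig, 0), end + spec.margin)
    ref = {}
    for contig in sorted(lengths):
        n = lengths[contig]
        seq = list(rng.choice(_BASES, size=n))
        target = int(spec.repeat_fraction * n)
        covered = 0
        while covered < target:
            unit_len = int(rng.integers(1, 4))
            reps = int(rng.integers(3, 7))
            tract = unit_len * reps
            start = int(rng.integers(0, max(1, n - tract)))
            unit = list(rng.choice(_BASES, size=unit_len))
            seq[start:start + tract] = unit * reps
            covered += tract
        ref[contig] = "".join(seq)
    return ref


def write_fasta(reference: Dict[str, str], path, width: int = 60) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "wt", encoding="utf-8") as fh:
        for contig in sorted(reference):
            fh.write(f">{contig}\n")
            seq = reference[contig]
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
    return path


# ---------------------------------------------------------------------------
# trio generation


@dataclass
class _Site:
    gene: str
    category: str
    chrom: str
    pos: int
    ref: str
    alts: Tuple[str, ...]
    child: str          # GT tokens
    father: Optional[str]    # None = no parental record / coverage hole
    mother: Optional[str]
    term: str
    impact: str          # raw ANN impact (MODERATE not yet mapped)
    maf: float
    cadd: float
    expected_kind: str   # ch | hom_alt | de_novo | none
    reportable: bool
    filter_fail: str     # "." or mode


def _other_base(rng, base: str) -> str:
    choices = [b for b in "ACGT" if b != base]
    return choices[int(rng.integers(0, 3))]


def _passing_values(rng, spec: FixtureSpec):
    maf = float(rng.uniform(*spec.maf_range))
    cadd = float(rng.uniform(*spec.cadd_range))
    impact = "HIGH" if rng.integers(0, 2) else "MODERATE"
    return maf, cadd, impact, "missense_variant" if impact == "MODERATE" else "stop_gained"


def _apply_filter_fail(rng, site: _Site, mode: str) -> _Site:
    if mode == "maf":
        return replace(site, maf=float(rng.uniform(0.02, 0.2)), filter_fail=mode)
    if mode == "cadd":
        return replace(site, cadd=float(rng.uniform(0.0, 10.0)), filter_fail=mode)
    if mode == "exonic":
        return replace(site, term="intron_variant", filter_fail=mode)
    if mode == "impact":
        return replace(site, term="missense_variant", impact="LOW", filter_fail=mode)
    raise PlanError(f"unknown filter-fail mode {mode!r}")


def _plant_gene(rng, spec: FixtureSpec, pg: PlantedGene, contig: str,
                start: int, end: int, seq: str) -> List[_Site]:
    usable = end - start - 40
    n_slots = max(spec.n_sites_per_gene, 2)
    spacing = max(4, usable // n_slots)
    positions = [start + 20 + k * spacing for k in range(n_slots)]

    def snv(pos, child, father, mother, kind="none", reportable=False):
        base = seq[pos - 1]
        alt = _other_base(rng, base)
        maf, cadd, impact, term = _passing_values(rng, spec)
        return _Site(pg.gene, pg.category, contig, pos, base, (alt,),
                     child, father, mother, term, impact, maf, cadd,
                     kind, reportable, ".")

    cat = pg.category
    sites: List[_Site] = []
    if cat == "trans_pair":
        sites.append(snv(positions[0], "0/1", "1/1", "0/0", "ch", True))
        sites.append(snv(positions[1], "0/1", "0/0", "1/1", "ch", True))
    elif cat == "cis_pair":
        sites.append(snv(positions[0], "0/1", "1/1", "0/0"))
        sites.append(snv(positions[1], "0/1", "1/1", "0/0"))
    elif cat == "hom_alt":
        sites.append(snv(positions[0], "1/1", "0/1", "0/1", "hom_alt", True))
    elif cat == "de_novo":
        sites.append(snv(positions[0], "0/1", "0/0", "0/0", "de_novo", True))
    elif cat == "mendelian_error":
        sites.append(snv(positions[0], "1/1", "0/0", "0/1"))
    elif cat == "ambiguous":
        sites.append(snv(positions[0], "0/1", "0/1", "0/1"))
    elif cat == "multiallelic":
        pos = positions[0]
        base = seq[pos - 1]
        alt1 = _other_base(rng, base)
        alt2 = next(b for b in "ACGT" if b not in (base, alt1))
        maf, cadd, impact, term = _passing_values(rng, spec)
        sites.append(_Site(pg.gene, cat, contig, pos, base, (alt1, alt2),
                           "1/2", None, None, term, impact, maf, cadd,
                           "none", False, "."))
    elif cat == "duplicate":
        pos = positions[0]
        s1 = snv(pos, "0/1", "1/1", "0/0")
        base = seq[pos - 1]
        alt2 = next(b for b in "ACGT" if b not in (base, s1.alts[0]))
        s2 = replace(s1, alts=(alt2,), father=None, mother=None)
        sites.extend([s1, s2])
    elif cat == "parents_missing":
        sites.append(replace(snv(positions[0], "0/1", None, None), father=None, mother=None))
    if pg.filter_fail is not None:
        sites[0] = _apply_filter_fail(rng, sites[0], pg.filter_fail)
        if sites[0].expected_kind != "none":
            sites = [replace(s, reportable=False) for s in sites]
    # Mendelian-consistent, filter-failing fillers (non-exonic MODIFIER)
    used = {s.pos for s in sites}
    for pos in positions:
        if len(sites) >= spec.n_sites_per_gene or pos in used:
            continue
        maf = float(rng.uniform(*spec.maf_range))
        cadd = float(rng.uniform(*spec.cadd_range))
        base = seq[pos - 1]
        sites.append(_Site(pg.gene, "filler", contig, pos, base,
                           (_other_base(rng, base),), "0/1", "1/1", "0/0",
                           "intron_variant", "MODIFIER", maf, cadd,
                           "none", False, "."))
    return sites


def _plant_denormalized_indel(rng, spec: FixtureSpec, pg: PlantedGene,
                              contig: str, start: int, seq: str,
                              taken: set) -> Optional[_Site]:
    """A one-base deletion written with a shared trailing base (so the
    left-aligner has work), placed in the intergenic margin; skipped when
    left-alignment would land it on an existing site."""
    pos = start - 30
    if pos < 2 or pos + 2 > len(seq):
        return None
    ref = seq[pos - 1: pos + 2]            # S[p] S[p+1] S[p+2] (1-based p=pos)
    alt = seq[pos - 1] + seq[pos + 1]      # deletes the middle base
    if alt == ref:
        return None
    try:
        npos, _, _ = normalize_variant(pos, ref, (alt,), seq)
    except Exception:
        return None
    if any((contig, p) in taken for p in (pos, npos)):
        return None
    maf = float(rng.uniform(*spec.maf_range))
    cadd = float(rng.uniform(*spec.cadd_range))
    return _Site(pg.gene, "indel_denorm", contig, pos, ref, (alt,),
                 "0/1", "1/1", "0/0", "intron_variant", "MODIFIER",
                 maf, cadd, "none", False, ".")


def _ann_value(site: _Site) -> str:
    parts = []
    for alt in site.alts:
        parts.append("|".join([
            alt, site.term, site.impact, site.gene, f"{site.gene}_ID",
            "transcript", f"TX_{site.gene}", "protein_coding",
        ]))
    return ",".join(parts)


def _member_record(site: _Site, member: str, gt_token: str) -> VariantRecord:
    info = {}
    if member == CHILD:
        info = {
            "ANN": _ann_value(site),
            "MAF": f"{site.maf:.6f}",
            "CADD": f"{site.cadd:.2f}",
        }
    return VariantRecord(
        chrom=site.chrom, pos=site.pos, ref=site.ref, alts=site.alts,
        qual=50.0, filter="PASS", info=info,
        genotypes={member: Genotype.from_token(gt_token)},
    )


def _coverage_blocks(member: str, interval: Tuple[str, int, int],
                     holes: set, seq: str) -> List[VariantRecord]:
    """Maximal <NON_REF> reference blocks over an interval, skipping holes
    (variant positions and planted no-coverage sites)."""
    contig, start, end = interval
    blocks = []
    run_start = None
    for p in range(start, end + 2):
        in_hole = p > end or (contig, p) in holes
        if in_hole:
            if run_start is not None:
                blocks.append(VariantRecord(
                    chrom=contig, pos=run_start, ref=seq[run_start - 1],
                    alts=(NON_REF_ALT,), qual=None, filter=".",
                    info={"END": str(p - 1)},
                    genotypes={member: Genotype(0, 0)},
                ))
                run_start = None
        elif run_start is None:
            run_start = p
    return blocks


def generate_trio(spec: FixtureSpec, reference: Dict[str, str], out_dir,
                  mode: str = "vcf") -> Dict[str, object]:
    """Write trio VCF/gVCF files, PED, truth table and GDI/length tables.

    In ``vcf`` mode parental homozygous-reference calls are explicit 0/0
    records (a sites-only VCF cannot otherwise distinguish hom-ref from
    missing); in ``gvcf`` mode they are expressed as <NON_REF> coverage
    blocks, and the child additionally carries non-variant blocks that the
    harmonization stage must strip.
    """
    if mode not in ("vcf", "gvcf"):
        raise PlanError(f"mode must be 'vcf' or 'gvcf', got {mode!r}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed + 1)
    layout = _gene_layout(spec)
    plan = spec.plan()

    sites: List[_Site] = []
    taken: set = set()
    for pg in plan:
        contig, start, end = layout[pg.gene]
        gene_sites = _plant_gene(rng, spec, pg, contig, start, end, reference[contig])
        sites.extend(gene_sites)
        taken.update((s.chrom, s.pos) for s in gene_sites)
    for pg in plan:
        if pg.category != "ambiguous":
            continue
        contig, start, end = layout[pg.gene]
        indel = _plant_denormalized_indel(rng, spec, pg, contig, start,
                                          reference[contig], taken)
        if indel is not None:
            sites.append(indel)
            taken.add((indel.chrom, indel.pos))

    child_records = []
    father_records = []
    mother_records = []
    for s in sites:
        child_records.append(_member_record(s, CHILD, s.child))
        if s.father is not None:
            father_records.append(_member_record(s, FATHER, s.father))
        if s.mother is not None:
            mother_records.append(_member_record(s, MOTHER, s.mother))

    if mode == "gvcf":
        intervals = {}
        for pg in plan:
            contig, start, end = layout[pg.gene]
            intervals[pg.gene] = (contig, max(1, start - 45), end)
        child_pos = {(r.chrom, r.pos) for r in child_records}
        father_pos = {(r.chrom, r.pos) for r in father_records}
        mother_pos = {(r.chrom, r.pos) for r in mother_records}
        no_cov = {(s.chrom, s.pos) for s in sites if s.category == "parents_missing"}
        for gene, interval in intervals.items():
            seq = reference[interval[0]]
            child_records.extend(_coverage_blocks(CHILD, interval, child_pos, seq))
            father_records.extend(_coverage_blocks(
                FATHER, interval, father_pos | no_cov, seq))
            mother_records.extend(_coverage_blocks(
                MOTHER, interval, mother_pos | no_cov, seq))

    for records in (child_records, father_records, mother_records):
        records.sort(key=record_sort_key)

    lengths = {c: len(s) for c, s in reference.items()}
    paths = {
        # the child deliberately uses the chr-prefixed contig dialect while
        # the parents use the bare one, exercising dialect harmonization
        "child": write_vcf(child_records, [CHILD], out_dir / "child.vcf",
                           chr_prefix=True, contig_lengths=lengths),
        "father": write_vcf(father_records, [FATHER], out_dir / "father.vcf",
                            contig_lengths=lengths),
        "mother": write_vcf(mother_records, [MOTHER], out_dir / "mother.vcf",
                            contig_lengths=lengths),
    }

    ped_path = out_dir / "trio.ped"
    ped_path.write_text(
        f"FAM001 {CHILD} {FATHER} {MOTHER} 0 2\n"
        f"FAM001 {FATHER} 0 0 1 1\n"
        f"FAM001 {MOTHER} 0 0 2 1\n",
        encoding="utf-8",
    )
    paths["ped"] = ped_path

    truth_path = out_dir / "truth.tsv"
    with open(truth_path, "wt", encoding="utf-8") as fh:
        fh.write("gene\tcategory\tchrom\tpos\tref\talt\tchild_gt\tfather_gt\t"
                 "mother_gt\texpected_kind\treportable\tfilter_fail\n")
        for s in sites:
            fh.write("\t".join([
                s.gene, s.category, s.chrom, str(s.pos), s.ref,
                ",".join(s.alts), s.child,
                s.father if s.father is not None else ".",
                s.mother if s.mother is not None else ".",
                s.expected_kind, "1" if s.reportable else "0", s.filter_fail,
            ]) + "\n")
    paths["truth"] = truth_path

    gdi_path = out_dir / "gdi.tsv"
    len_path = out_dir / "gene_lengths.tsv"
    with open(gdi_path, "wt", encoding="utf-8") as gfh, \
            open(len_path, "wt", encoding="utf-8") as lfh:
        gfh.write("gene\tgdi_score\n")
        lfh.write("gene\tgene_length\n")
        for i, pg in enumerate(plan):
            score = float(rng.uniform(2.0, 13.0)) if i % 2 == 0 \
                else float(rng.uniform(14.0, 60.0))
            gfh.write(f"{pg.gene}\t{score:.2f}\n")
            lfh.write(f"{pg.gene}\t{int(rng.integers(2_000, 120_000))}\n")
    paths["gdi"] = gdi_path
    paths["gene_lengths"] = len_path
    paths["sites"] = sites
    return paths


def simulate(spec: FixtureSpec, out_dir, mode: str = "vcf") -> Dict[str, object]:
    """Generate reference + trio + tables into ``out_dir``; returns paths."""
    out_dir = Path(out_dir)
    reference = generate_reference(spec)
    paths = generate_trio(spec, reference, out_dir, mode=mode)
    paths["fasta"] = write_fasta(reference, out_dir / "ref.fa")
    paths["reference"] = reference
    return paths


def read_truth(path) -> List[dict]:
    rows = []
    with open(path, "rt", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            rows.append(dict(zip(header, line.rstrip("\n").split("\t"))))
    return rows
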