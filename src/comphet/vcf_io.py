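"""VCF/gVCF and PED input/output and the core variant data model.

The model is deliberately text-faithful: INFO values are carried as opaque
strings so that unknown keys survive a read/write round trip unchanged, and
genotypes keep their phase separator and half-missing alleles exactly as
written.  Contig names are normalized internally to the bare dialect
("1".."22", "X", "Y", "MT"); a leading ``chr`` seen on input can be restored
on output via :func:`write_vcf`'s ``chr_prefix`` flag.  All coordinates are
1-based inclusive (VCF convention).
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from .errors import PedigreeError, VcfOrderError, VcfParseError

__all__ = [
    "MISSING",
    "Genotype",
    "VariantRecord",
    "TrioContext",
    "read_vcf",
    "write_vcf",
    "read_ped",
    "sniff_chr_prefix",
    "contig_sort_key",
    "record_sort_key",
    "NON_REF_ALT",
]

#: Sentinel for a missing allele ("." in a GT field).
MISSING = None

#: Symbolic allele used by gVCF reference blocks.
NON_REF_ALT = "<NON_REF>"

_CANONICAL_CONTIGS = {str(i): i for i in range(1, 23)}
_CANONICAL_CONTIGS.update({"X": 23, "Y": 24, "MT": 25, "M": 25})


def contig_sort_key(chrom: str):
    """Sort key placing 1..22, X, Y, MT first and other contigs after,
    lexicographically."""
    rank = _CANONICAL_CONTIGS.get(chrom)
    if rank is not None:
        return (0, rank, "")
    return (1, 0, chrom)


def normalize_contig(chrom: str) -> str:
    """Strip a leading ``chr``/``Chr`` prefix, mapping e.g. chr1 -> 1."""
    if chrom[:3].lower() == "chr":
        return chrom[3:]
    return chrom


@dataclass(frozen=True)
class Genotype:
    """A diploid genotype: two allele indices (``None`` = missing) and a
    phase flag.

    When ``phased`` is true the pair is ordered: ``allele_a`` is the paternal
    haplotype and ``allele_b`` the maternal haplotype (toolkit convention).
    """

    allele_a: Optional[int]
    allele_b: Optional[int]
    phased: bool = False

    def __post_init__(self):
        for a in (self.allele_a, self.allele_b):
            if a is not None and a < 0:
                raise ValueError(f"negative allele index {a!r}")

    @property
    def alleles(self) -> tuple:
        return (self.allele_a, self.allele_b)

    @property
    def is_missing(self) -> bool:
        """Fully missing ("./.")."""
        return self.allele_a is None and self.allele_b is None

    @property
    def has_missing(self) -> bool:
        return self.allele_a is None or self.allele_b is None

    @property
    def is_het(self) -> bool:
        a, b = self.alleles
        return a is not None and b is not None and a != b

    @property
    def alt_count(self) -> int:
        """Number of non-reference alleles among the called ones."""
        return sum(1 for a in self.alleles if a is not None and a > 0)

    def sorted_alleles(self) -> tuple:
        """Allele multiset as a sorted tuple; missing alleles sort last."""
        return tuple(sorted(self.alleles, key=lambda a: (a is None, a)))

    @classmethod
    def from_token(cls, token: str) -> "Genotype":
        """Parse a GT token such as ``0/1``, ``1|0``, ``./.`` or ``./1``."""
        if "|" in token:
            parts, phased = token.split("|"), True
        elif "/" in token:
            parts, phased = token.split("/"), False
        else:
            raise VcfParseError(f"genotype token {token!r} is not diploid")
        if len(parts) != 2:
            raise VcfParseError(f"genotype token {token!r} is not diploid")
        alleles = []
        for p in parts:
            if p == ".":
                alleles.append(None)
            else:
                try:
                    alleles.append(int(p))
                except ValueError as exc:
                    raise VcfParseError(f"bad allele index {p!r} in {token!r}") from exc
        return cls(alleles[0], alleles[1], phased)

    def token(self) -> str:
        sep = "|" if self.phased else "/"
        return sep.join("." if a is None else str(a) for a in self.alleles)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.token()


@dataclass
class VariantRecord:
    """One VCF data line.

    ``alts`` may be empty only for gVCF reference blocks (which carry an END
    key in INFO or span a single base).  ``info`` maps keys to opaque string
    values, or ``True`` for flag keys.  ``genotypes`` maps sample id to
    :class:`Genotype`.
    """

    chrom: str
    pos: int
    ref: str
    alts: tuple = ()
    id: Optional[str] = None
    qual: Optional[float] = None
    filter: str = "."
    info: dict = field(default_factory=dict)
    genotypes: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not self.ref:
            raise ValueError("ref allele must be non-empty")
        self.alts = tuple(self.alts)
        for alt in self.alts:
            if not alt:
                raise ValueError("alt allele must be non-empty")
            if alt == self.ref:
                raise ValueError(f"alt equals ref ({alt!r}) at {self.chrom}:{self.pos}")

    @property
    def is_non_variant(self) -> bool:
        """True for gVCF reference blocks (<NON_REF>-only or alt-less)."""
        return len(self.alts) == 0 or self.alts == (NON_REF_ALT,)

    @property
    def end(self) -> int:
        """Last reference position covered; honours gVCF END."""
        if "END" in self.info:
            return int(self.info["END"])
        return self.pos + len(self.ref) - 1

    @property
    def key(self) -> tuple:
        return (self.chrom, self.pos)

    def replace(self, **kw) -> "VariantRecord":
        new = replace(self, **{k: v for k, v in kw.items() if k not in ("info", "genotypes")})
        new.info = dict(kw.get("info", self.info))
        new.genotypes = dict(kw.get("genotypes", self.genotypes))
        return new


def record_sort_key(rec: VariantRecord):
    return (contig_sort_key(rec.chrom), rec.pos)


@dataclass(frozen=True)
class TrioContext:
    """Pedigree roles mapped to sample identifiers."""

    child_id: str
    father_id: str
    mother_id: str

    def __post_init__(self):
        ids = (self.child_id, self.father_id, self.mother_id)
        if len(set(ids)) != 3:
            raise PedigreeError(f"trio sample ids must be distinct, got {ids}")

    @property
    def sample_ids(self) -> tuple:
        return (self.child_id, self.father_id, self.mother_id)


# ---------------------------------------------------------------------------
# INFO field serialization


def _parse_info(text: str) -> dict:
    info: dict = {}
    if text == "." or text == "":
        return info
    for chunk in text.split(";"):
        if not chunk:
            continue
        if "=" in chunk:
            k, v = chunk.split("=", 1)
            info[k] = v
        else:
            info[chunk] = True
    return info


def _format_info(info: Mapping) -> str:
    if not info:
        return "."
    parts = []
    for k, v in info.items():
        if v is True:
            parts.append(k)
        else:
            parts.append(f"{k}={v}")
    return ";".join(parts)


# ---------------------------------------------------------------------------
# Reading


def _open_text(path) -> io.TextIOBase:
    path = Path(path)
    if path.suffix == ".gz":
        return io.TextIOWrapper(gzip.open(path, "rb"), encoding="utf-8")
    return open(path, "rt", encoding="utf-8")


def sniff_chr_prefix(path) -> bool:
    """True if the first data line of the file uses ``chr``-prefixed contigs."""
    with _open_text(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            return line[:3].lower() == "chr"
    return False


def read_vcf(path, mode: str = "vcf", sort: bool = False):
    """Read a VCF or gVCF file.

    Parameters
    ----------
    path:
        Plain or gzip/bgzip-compressed VCF text file.
    mode:
        ``"vcf"`` or ``"gvcf"``.  The parser is identical; the flag is kept
        for pipeline bookkeeping (gVCF reference blocks are recognized from
        their <NON_REF> alt / END key either way).
    sort:
        If true, out-of-order input is sorted instead of raising
        :class:`VcfOrderError`.

    Returns
    -------
    (records, samples):
        Records in (contig, position) order and the header sample-id list.
    """
    if mode not in ("vcf", "gvcf"):
        raise ValueError(f"mode must be 'vcf' or 'gvcf', got {mode!r}")
    records = []
    samples: list = []
    saw_header = False
    ordered = True
    last_key = None
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line:
                continue
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                cols = line.split("\t")
                if len(cols) < 8:
                    raise VcfParseError(f"line {lineno}: truncated #CHROM header")
                samples = cols[9:]
                saw_header = True
                continue
            if not saw_header:
                raise VcfParseError(f"line {lineno}: data line before #CHROM header")
            rec = _parse_data_line(line, lineno, samples)
            k = record_sort_key(rec)
            if last_key is not None and k < last_key:
                ordered = False
            last_key = k
            records.append(rec)
    if not ordered:
        if not sort:
            raise VcfOrderError(f"{path}: records not sorted by (contig, pos); pass sort=True")
        records.sort(key=record_sort_key)
    return records, samples


def _parse_data_line(line: str, lineno: int, samples: Sequence[str]) -> VariantRecord:
    cols = line.split("\t")
    if len(cols) < 8:
        raise VcfParseError(f"line {lineno}: expected >= 8 tab-separated fields, got {len(cols)}")
    chrom = normalize_contig(cols[0])
    try:
        pos = int(cols[1])
    except ValueError as exc:
        raise VcfParseError(f"line {lineno}: bad POS {cols[1]!r}") from exc
    vid = None if cols[2] == "." else cols[2]
    ref = cols[3]
    alts = () if cols[4] == "." else tuple(cols[4].split(","))
    if cols[5] == ".":
        qual = None
    else:
        try:
            qual = float(cols[5])
        except ValueError as exc:
            raise VcfParseError(f"line {lineno}: bad QUAL {cols[5]!r}") from exc
    filt = cols[6]
    info = _parse_info(cols[7])
    genotypes: dict = {}
    if samples:
        if len(cols) < 10:
            raise VcfParseError(f"line {lineno}: header declares samples but line has no FORMAT")
        fmt = cols[8].split(":")
        try:
            gt_idx = fmt.index("GT")
        except ValueError as exc:
            raise VcfParseError(f"line {lineno}: FORMAT lacks GT") from exc
        if len(cols) != 9 + len(samples):
            raise VcfParseError(
                f"line {lineno}: {len(cols) - 9} sample columns for {len(samples)} samples"
            )
        for sample, token in zip(samples, cols[9:]):
            fields = token.split(":")
            if gt_idx >= len(fields):
                raise VcfParseError(f"line {lineno}: sample {sample} lacks a GT value")
            try:
                genotypes[sample] = Genotype.from_token(fields[gt_idx])
            except VcfParseError as exc:
                raise VcfParseError(f"line {lineno}: {exc}") from exc
    try:
        return VariantRecord(
            chrom=chrom, pos=pos, id=vid, ref=ref, alts=alts,
            qual=qual, filter=filt, info=info, genotypes=genotypes,
        )
    except ValueError as exc:
        raise VcfParseError(f"line {lineno}: {exc}") from exc


# ---------------------------------------------------------------------------
# Writing

_KNOWN_INFO_HEADERS = {
    "END": ('Number=1,Type=Integer', "End position of a gVCF reference block"),
    "MAF": ('Number=1,Type=Float', "Global minor allele frequency"),
    "CADD": ('Number=1,Type=Float', "CADD phred-scaled deleteriousness score"),
    "ANN": ('Number=.,Type=String', "Functional annotations (SnpEff ANN format)"),
    "PSTAT": ('Number=1,Type=String', "Mendelian phasing status flag"),
}


def _format_qual(q: Optional[float]) -> str:
    if q is None:
        return "."
    if float(q).is_integer():
        return str(int(q))
    return repr(round(float(q), 6))


def write_vcf(records: Iterable[VariantRecord], samples: Sequence[str], path,
              chr_prefix: bool = False, contig_lengths: Optional[Mapping[str, int]] = None):
    """Write records to a VCF v4.2 text file.

    Records must already be sorted; phased genotypes are serialized with
    ``|``, unphased with ``/``.  ``chr_prefix`` restores a ``chr``-prefixed
    contig dialect on output.
    """
    records = list(records)
    keys = [record_sort_key(r) for r in records]
    if keys != sorted(keys):
        raise VcfOrderError("records must be sorted before writing")
    info_keys: list = []
    for r in records:
        for k in r.info:
            if k not in info_keys:
                info_keys.append(k)
    contigs: list = []
    for r in records:
        if r.chrom not in contigs:
            contigs.append(r.chrom)
    contigs.sort(key=contig_sort_key)

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=comphet\n")
        for c in contigs:
            name = f"chr{c}" if chr_prefix else c
            if contig_lengths and c in contig_lengths:
                fh.write(f"##contig=<ID={name},length={contig_lengths[c]}>\n")
            else:
                fh.write(f"##contig=<ID={name}>\n")
        for k in info_keys:
            flag = any(r.info.get(k) is True for r in records)
            if flag:
                spec, desc = 'Number=0,Type=Flag', "Flag"
            else:
                spec, desc = _KNOWN_INFO_HEADERS.get(k, ('Number=.,Type=String', "Opaque value"))
            fh.write(f'##INFO=<ID={k},{spec},Description="{desc}">\n')
        if samples:
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"]
        if samples:
            header += ["FORMAT", *samples]
        fh.write("\t".join(header) + "\n")
        for r in records:
            _check_serializable(r)
            chrom = f"chr{r.chrom}" if chr_prefix else r.chrom
            cols = [
                chrom,
                str(r.pos),
                r.id if r.id is not None else ".",
                r.ref,
                ",".join(r.alts) if r.alts else ".",
                _format_qual(r.qual),
                r.filter,
                _format_info(r.info),
            ]
            if samples:
                cols.append("GT")
                for s in samples:
                    gt = r.genotypes.get(s, Genotype(MISSING, MISSING))
                    cols.append(gt.token())
            fh.write("\t".join(cols) + "\n")
    return path


def _check_serializable(rec: VariantRecord):
    for k, v in rec.info.items():
        if v is True:
            continue
        text = str(v)
        if any(c in text for c in ";\t\n "):
            raise VcfParseError(
                f"INFO value for {k!r} at {rec.chrom}:{rec.pos} is not serializable: {text!r}"
            )


# ---------------------------------------------------------------------------
# PED


def read_ped(path) -> list:
    """Parse a 6-column PED file into one :class:`TrioContext` per complete
    trio (child row with both parental ids non-zero).

    Raises :class:`PedigreeError` when no complete trio exists or the
    parentage graph is circular.
    """
    rows = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split()
            if len(cols) < 6:
                raise PedigreeError(f"line {lineno}: PED rows need 6 columns, got {len(cols)}")
            rows.append(cols)
    parent_of = {c[1]: (c[2], c[3]) for c in rows}
    # circularity check: an individual may not be its own ancestor
    for start in parent_of:
        frontier = [start]
        seen = set()
        while frontier:
            ind = frontier.pop()
            for p in parent_of.get(ind, ("0", "0")):
                if p == "0":
                    continue
                if p == start:
                    raise PedigreeError(f"circular parentage involving {start!r}")
                if p not in seen:
                    seen.add(p)
                    frontier.append(p)
    trios = []
    for cols in rows:
        child, father, mother = cols[1], cols[2], cols[3]
        if father != "0" and mother != "0":
            trios.append(TrioContext(child_id=child, father_id=father, mother_id=mother))
    if not trios:
        raise PedigreeError(f"{path}: no complete trio (child with both parents) found")
    return trios
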