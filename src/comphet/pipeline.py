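"""End-to-end orchestration: prep -> phase -> normalize -> store -> identify -> gdi.

Each stage is an ordinary function over records and writes its own output
file, so any stage can be re-run from the previous stage's VCF.  A run
manifest (JSON) captures every threshold and decision flag that affects the
output.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Optional

from . import annotate_query, identify, normalize, phasing, trio_prep, vcf_io
from .errors import ModeError
from .vcf_io import TrioContext, normalize_contig, record_sort_key

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "load_reference"]


def load_reference(fasta_path) -> Dict[str, str]:
    """FASTA -> {normalized contig name: sequence string}."""
    from pyfaidx import Fasta
    fa = Fasta(str(fasta_path))
    return {normalize_contig(name): str(fa[name][:]) for name in fa.keys()}


@dataclass
class PipelineConfig:
    vcf_child: str
    fasta: str
    out_dir: str
    vcf_father: Optional[str] = None
    vcf_mother: Optional[str] = None
    ped: Optional[str] = None
    mode: str = "vcf"                      # vcf | gvcf
    maf_max: float = 0.01
    cadd_min: float = 15.0
    gdi_threshold: float = identify.GDI_DAMAGE_THRESHOLD
    require_exonic: bool = True
    allowed_impacts: tuple = ("HIGH", "MED")
    require_carrier_parents: bool = False
    maf_key: str = "MAF"
    cadd_key: str = "CADD"
    gdi_table: Optional[str] = None
    length_table: Optional[str] = None
    threads: int = 1

    @property
    def trio_mode(self) -> bool:
        return self.ped is not None


def run_pipeline(cfg: PipelineConfig) -> Dict[str, object]:
    """Execute the full pipeline; returns a summary dict (also written as
    ``manifest.json`` in the output directory)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    trio: Optional[TrioContext] = None
    if cfg.trio_mode:
        if not (cfg.vcf_father and cfg.vcf_mother):
            raise ModeError("trio mode requires father and mother VCFs")
        trio = vcf_io.read_ped(cfg.ped)[0]

    chr_prefix = vcf_io.sniff_chr_prefix(cfg.vcf_child)
    child, child_samples = vcf_io.read_vcf(cfg.vcf_child, mode=cfg.mode)
    child = _restrict_sample(child, child_samples, trio.child_id if trio else None)

    # -- prep: harmonize, merge, site hygiene ------------------------------
    if trio is not None:
        father, father_samples = vcf_io.read_vcf(cfg.vcf_father, mode=cfg.mode)
        mother, mother_samples = vcf_io.read_vcf(cfg.vcf_mother, mode=cfg.mode)
        father = _restrict_sample(father, father_samples, trio.father_id)
        mother = _restrict_sample(mother, mother_samples, trio.mother_id)
        child_h, father_h, mother_h = trio_prep.harmonize_trio(
            child, father, mother, mode=cfg.mode)
        merged = trio_prep.combine_trio(child_h, father_h, mother_h, trio)
        samples = list(trio.sample_ids)
    else:
        merged = [r for r in child if not r.is_non_variant]
        samples = child_samples
    vcf_io.write_vcf(merged, samples, out / "merged.vcf", chr_prefix=chr_prefix)

    filtered, removal_log = trio_prep.filter_sites(merged, trio)
    trio_prep.write_removal_log(removal_log, out / "removal_log.tsv")
    vcf_io.write_vcf(filtered, samples, out / "filtered.vcf", chr_prefix=chr_prefix)

    reference = load_reference(cfg.fasta)

    # -- phase: per-chromosome Mendelian phasing + congruence repair -------
    if trio is not None:
        per_contig = phasing.split_by_chromosome(filtered)
        phased_map = {}
        site_log = []
        for contig in sorted(per_contig, key=vcf_io.contig_sort_key):
            phased_map[contig], contig_log = phasing.phase_records(
                per_contig[contig], trio, reference)
            site_log.extend(contig_log)
        phased = phasing.concatenate_chromosomes(phased_map)
        phasing.write_site_log(site_log, out / "site_log.tsv")
    else:
        phased, site_log = filtered, []
    vcf_io.write_vcf(phased, samples, out / "phased.vcf", chr_prefix=chr_prefix)

    # -- normalize ----------------------------------------------------------
    normalized = []
    for rec in phased:
        pos, ref, alts = normalize.normalize_variant(
            rec.pos, rec.ref, rec.alts, reference[rec.chrom])
        normalized.append(rec.replace(pos=pos, ref=ref, alts=alts))
    normalized.sort(key=record_sort_key)
    vcf_io.write_vcf(normalized, samples, out / "normalized.vcf", chr_prefix=chr_prefix)

    # -- store + identify ---------------------------------------------------
    store = annotate_query.build_store(
        normalized, trio=trio, maf_key=cfg.maf_key, cadd_key=cfg.cadd_key)
    annotate_query.export_store_tsv(store, out / "store.tsv")
    thresholds = identify.FilterThresholds(
        maf_max=cfg.maf_max, cadd_min=cfg.cadd_min,
        allowed_impacts=frozenset(cfg.allowed_impacts),
        require_exonic=cfg.require_exonic)

    reports = {}
    if trio is not None:
        reports["ch"] = identify.find_compound_het(store, thresholds)
        reports["denovo"] = identify.find_de_novo(store, thresholds)
    reports["homalt"] = identify.find_hom_alt(
        store, thresholds, require_carrier_parents=cfg.require_carrier_parents)

    # -- gdi join ------------------------------------------------------------
    gdi_table = identify.load_gdi_table(cfg.gdi_table) if cfg.gdi_table else None
    length_table = identify.load_length_table(cfg.length_table) if cfg.length_table else None
    for kind, rs in reports.items():
        if gdi_table is not None:
            rs = identify.annotate_gdi(rs, gdi_table, length_table,
                                       damage_threshold=cfg.gdi_threshold)
            reports[kind] = rs
        identify.write_reports(rs, store, out / f"{kind}.tsv")

    summary = {
        "config": {
            "mode": cfg.mode,
            "trio": trio.sample_ids if trio else None,
            "maf_max": cfg.maf_max,
            "cadd_min": cfg.cadd_min,
            "allowed_impacts": sorted(cfg.allowed_impacts),
            "require_exonic": cfg.require_exonic,
            "require_carrier_parents": cfg.require_carrier_parents,
            "gdi_threshold": cfg.gdi_threshold,
            "maf_key": cfg.maf_key,
            "cadd_key": cfg.cadd_key,
            "gdi_table": cfg.gdi_table,
            "length_table": cfg.length_table,
            "chr_prefix": chr_prefix,
            "merge_backend": "native",
            "threads": cfg.threads,
        },
        "counts": {
            "input_child_records": len(child),
            "merged": len(merged),
            "removed": dict(Counter(reason for _, _, reason in removal_log)),
            "kept_after_hygiene": len(filtered),
            "phase_status": dict(Counter(status for _, _, status in site_log)),
            "normalized": len(normalized),
            "store_entries": len(store.variants),
            "reports": {k: len(v) for k, v in reports.items()},
        },
        "outputs": {k: str(out / f"{k}.tsv") for k in reports},
    }
    (out / "manifest.json").write_text(json.dumps(summary, indent=2) + "\n",
                                       encoding="utf-8")
    summary["reports"] = reports
    return summary


def _restrict_sample(records, samples, sample_id):
    """Keep one member's genotype column; tolerates single-sample files
    whose header sample differs from the PED id by renaming it."""
    if sample_id is None or not samples:
        return records
    if sample_id in samples:
        keep = sample_id
    elif len(samples) == 1:
        keep = samples[0]
    else:
        raise ModeError(f"sample {sample_id!r} not found among {samples}")
    out = []
    for r in records:
        gt = r.genotypes.get(keep)
        out.append(r.replace(genotypes={sample_id: gt} if gt is not None else {}))
    return out
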