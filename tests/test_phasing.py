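from collections import Counter

import pytest

from comphet.errors import (ConcatenationError, ContractViolationError,
                            CoordinateError)
from comphet.phasing import (PhaseStatus, concatenate_chromosomes,
                             detect_mendelian_error, fix_ref_alt_congruence,
                             mendelian_phase_site, phase_records,
                             split_by_chromosome)
from comphet.vcf_io import Genotype, TrioContext, VariantRecord

from helpers import all_trio_genotypes, oracle_status, oracle_transmissions

TRIO = TrioContext(child_id="C", father_id="F", mother_id="M")

G = Genotype.from_token


# ---------------------------------------------------------------------------
# mendelian_phase_site


@pytest.mark.parametrize("child,father,mother,status,phase", [
    ("0/1", "0/0", "1/1", PhaseStatus.PHASED, (0, 1)),
    ("0/1", "1/1", "0/0", PhaseStatus.PHASED, (1, 0)),
    ("0/1", "0/1", "0/1", PhaseStatus.AMBIGUOUS, None),
    ("0/1", "0/0", "0/0", PhaseStatus.POTENTIAL_DE_NOVO, None),
    ("1/1", "0/0", "0/1", PhaseStatus.MENDELIAN_ERROR, None),
    ("0/0", "0/0", "0/0", PhaseStatus.PHASED, (0, 0)),
    ("1/1", "1/1", "1/1", PhaseStatus.PHASED, (1, 1)),
    ("0/1", "./.", "0/0", PhaseStatus.PHASED, (1, 0)),   # wildcard father forced
    ("0/1", "./.", "./.", PhaseStatus.AMBIGUOUS, None),
])
def test_phase_site_cases(child, father, mother, status, phase):
    res = mendelian_phase_site(G(child), G(father), G(mother))
    assert res.status == status
    if phase is not None:
        assert res.child_phased.phased
        assert res.child_phased.alleles == phase
    else:
        assert res.child_phased is None


def test_exhaustive_oracle_agreement():
    """Across every trio genotype combination, including missing and
    half-missing alleles, status agrees with the brute-force transmission
    enumeration oracle, and a phased call matches its unique assignment."""
    for child, father, mother in all_trio_genotypes(include_missing=True):
        res = mendelian_phase_site(child, father, mother)
        expected = oracle_status(child, father, mother)
        assert res.status == expected, (child, father, mother)
        if expected == PhaseStatus.PHASED:
            (assignment,) = oracle_transmissions(child, father, mother)
            assert res.child_phased.alleles == assignment
        err = detect_mendelian_error(child, father, mother)
        assert err == (len(oracle_transmissions(child, father, mother)) == 0)


def test_phasing_conserves_child_genotype_content():
    """Phasing reorders, never rewrites, the child's alleles."""
    for child, father, mother in all_trio_genotypes(include_missing=False):
        res = mendelian_phase_site(child, father, mother)
        if res.status == PhaseStatus.PHASED:
            assert sorted(res.child_phased.alleles) == sorted(child.alleles)


def test_phase_site_rejects_multiallelic_indices():
    with pytest.raises(ContractViolationError):
        mendelian_phase_site(G("1/2"), G("0/0"), G("0/0"))


@pytest.mark.parametrize("child,father,mother,expected", [
    ("1/1", "0/0", "0/1", True),    # father cannot transmit the alt
    ("0/1", "1/1", "0/0", False),   # forced 1|0
    ("0/0", "./.", "0/1", False),   # missing father unconstrained
])
def test_detect_mendelian_error_cases(child, father, mother, expected):
    assert detect_mendelian_error(G(child), G(father), G(mother)) is expected


# ---------------------------------------------------------------------------
# split / concatenate


def _rec(chrom, pos, **kw):
    defaults = dict(ref="A", alts=("G",))
    defaults.update(kw)
    return VariantRecord(chrom=chrom, pos=pos, **defaults)


def test_split_partitions_and_concat_inverts():
    records = [_rec("1", 10), _rec("1", 20), _rec("2", 5)]
    parts = split_by_chromosome(records)
    assert set(parts) == {"1", "2"}
    assert sum(len(v) for v in parts.values()) == len(records)
    assert all(r.chrom == c for c, rs in parts.items() for r in rs)
    assert concatenate_chromosomes(parts) == records


def test_split_empty_input():
    assert split_by_chromosome([]) == {}
    assert concatenate_chromosomes({}) == []


def test_concatenate_rejects_misfiled_records():
    with pytest.raises(ConcatenationError):
        concatenate_chromosomes({"1": [_rec("2", 5)]})


# ---------------------------------------------------------------------------
# REF/ALT congruence


REF = {"1": "ACGTACGTTT"}


def _site(pos, ref, alt, c="0|1", f="0/0", m="1/1"):
    return VariantRecord(chrom="1", pos=pos, ref=ref, alts=(alt,),
                         genotypes={"C": G(c), "F": G(f), "M": G(m)})


def test_congruent_record_unchanged():
    rec = _site(4, "T", "A")
    assert fix_ref_alt_congruence(rec, REF) is rec


def test_swapped_ref_alt_repaired_with_genotype_inversion():
    """reference has C at pos 2; a record claiming T->C there had its
    alleles switched: repair swaps them back and inverts every genotype,
    preserving phase order."""
    rec = _site(2, "T", "C", c="0|1", f="0/0", m="1/1")
    fixed = fix_ref_alt_congruence(rec, REF)
    assert (fixed.ref, fixed.alts) == ("C", ("T",))
    assert fixed.genotypes["C"] == Genotype(1, 0, phased=True)
    assert fixed.genotypes["F"] == Genotype(1, 1)
    assert fixed.genotypes["M"] == Genotype(0, 0)


def test_neither_allele_matches_removes_record():
    assert fix_ref_alt_congruence(_site(2, "T", "G"), REF) is None


def test_congruence_repair_is_idempotent():
    fixed = fix_ref_alt_congruence(_site(2, "T", "C"), REF)
    assert fix_ref_alt_congruence(fixed, REF) is fixed


def test_congruence_locus_beyond_contig_end():
    with pytest.raises(CoordinateError):
        fix_ref_alt_congruence(_site(10, "TTT", "T"), REF)


# ---------------------------------------------------------------------------
# phase_records composition


def test_phase_records_three_site_toy():
    records = [
        _site(1, "A", "G", c="0/1", f="1/1", m="0/0"),   # forced 1|0
        _site(4, "T", "C", c="0/1", f="0/1", m="0/1"),   # ambiguous
        _site(8, "T", "C", c="1/1", f="0/0", m="0/1"),   # mendelian error
    ]
    out, log = phase_records(records, TRIO, REF)
    assert len(out) == 2
    assert Counter(s for _, _, s in log) == {
        "phased": 1, "ambiguous": 1, "mendelian_error": 1}
    assert out[0].genotypes["C"] == Genotype(1, 0, phased=True)
    assert not out[1].genotypes["C"].phased
    assert out[1].info["PSTAT"] == "ambiguous"


def test_phase_records_all_homozygous_trio_phases_trivially():
    records = [_site(1, "A", "G", c="1/1", f="1/1", m="1/1"),
               _site(4, "T", "C", c="0/0", f="0/0", m="0/0")]
    out, log = phase_records(records, TRIO, REF)
    assert all(r.genotypes["C"].phased for r in out)
    assert all(s == "phased" for _, _, s in log)


def test_phase_records_retains_de_novo_unphased_and_flagged():
    records = [_site(1, "A", "G", c="0/1", f="0/0", m="0/0")]
    out, log = phase_records(records, TRIO, REF)
    (rec,) = out
    assert not rec.genotypes["C"].phased
    assert rec.info["PSTAT"] == "denovo"
    assert log == [("1", 1, PhaseStatus.POTENTIAL_DE_NOVO)]


def test_phase_records_logs_incongruent_and_repairs_before_error_check():
    """A swapped site that is Mendelian-consistent after repair must be
    repaired, not discarded as an error."""
    records = [
        _site(2, "T", "C", c="0/1", f="1/1", m="0/0"),   # swapped; consistent after repair
        _site(6, "A", "T", c="0/1", f="0/0", m="1/1"),   # neither matches reference (pos6=C)
    ]
    out, log = phase_records(records, TRIO, REF)
    assert [s for _, _, s in log] == ["phased", "incongruent"]
    (rec,) = out
    assert rec.ref == "C" and rec.alts == ("T",)


def test_phase_records_output_free_of_mendelian_errors(pipeline_vcf):
    """No retained site in a pipeline run is a Mendelian error, excluding
    flagged potential-de-novo sites."""
    from comphet.vcf_io import read_vcf
    import pathlib
    out_dir = pathlib.Path(pipeline_vcf["outputs"]["ch"]).parent
    records, samples = read_vcf(out_dir / "phased.vcf")
    for rec in records:
        if rec.info.get("PSTAT") == "denovo":
            continue
        assert not detect_mendelian_error(
            rec.genotypes["CHILD"], rec.genotypes["FATHER"], rec.genotypes["MOTHER"])
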