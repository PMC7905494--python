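import itertools
from importlib import resources

import pytest

from comphet.annotate_query import AnnotatedVariant, VariantStore, build_store
from comphet.errors import ModeError
from comphet.identify import (FilterThresholds, annotate_gdi, find_compound_het,
                              find_de_novo, find_hom_alt, load_gdi_table,
                              passes_filters)
from comphet.vcf_io import Genotype, TrioContext, VariantRecord

TRIO = TrioContext(child_id="C", father_id="F", mother_id="M")
T = FilterThresholds()  # maf<=0.01, cadd>=15, exonic, HIGH/MED

G = Genotype.from_token


def _av(pos, child, father="0/0", mother="0/0", gene="G1", maf=0.001,
        cadd=20.0, impact="MED", exonic=True, term="missense_variant"):
    rec = VariantRecord(chrom="1", pos=pos, ref="A", alts=("G",),
                        genotypes={"C": G(child), "F": G(father), "M": G(mother)})
    return AnnotatedVariant(record=rec, gene=gene, impact=impact, exonic=exonic,
                            maf=maf, cadd=cadd, annotation_term=term)


def _store(variants, trio=TRIO):
    store = VariantStore(variants=list(variants), trio=trio)
    store.by_gene = store.rebuild_index()
    return store


# ---------------------------------------------------------------------------
# filters


@pytest.mark.parametrize("kw,expected", [
    (dict(maf=0.005, cadd=20.0, impact="HIGH"), True),
    (dict(maf=0.02, cadd=20.0, impact="HIGH"), False),     # too common
    (dict(maf=0.005, cadd=10.0), False),                   # not deleterious enough
    (dict(maf=0.005, exonic=False), False),
    (dict(maf=0.005, impact="LOW"), False),
    (dict(maf=0.005, cadd=None), False),                   # fail-closed
    (dict(maf=None, cadd=20.0), False),                    # fail-closed
    (dict(maf=0.01, cadd=15.0), True),                     # bounds are inclusive
])
def test_passes_filters(kw, expected):
    assert passes_filters(_av(1, "0|1", **kw), T) is expected


def test_threshold_validation():
    with pytest.raises(ValueError):
        FilterThresholds(maf_max=1.5)
    with pytest.raises(ValueError):
        FilterThresholds(cadd_min=-1)
    with pytest.raises(ValueError):
        FilterThresholds(allowed_impacts=frozenset())


# ---------------------------------------------------------------------------
# compound het


def test_trans_pair_reported_with_inheritance_sides():
    store = _store([_av(10, "1|0"), _av(20, "0|1")])
    (rep,) = find_compound_het(store, T)
    assert rep.kind == "compound_het" and rep.gene == "G1"
    assert [v.pos for v in rep.variants] == [10, 20]
    assert rep.inheritance == ("paternal", "maternal")


def test_cis_pair_not_reported():
    assert find_compound_het(_store([_av(10, "1|0"), _av(20, "1|0")]), T) == []


def test_ch_exhaustive_child_phase_configurations():
    """Of the 16 ordered phased-genotype configurations of a 2-variant gene,
    exactly (0|1, 1|0) and (1|0, 0|1) yield a compound-het pair."""
    qualifying = []
    for g1, g2 in itertools.product(["0|0", "0|1", "1|0", "1|1"], repeat=2):
        store = _store([_av(10, g1), _av(20, g2)])
        if find_compound_het(store, T):
            qualifying.append((g1, g2))
    assert qualifying == [("0|1", "1|0"), ("1|0", "0|1")]


def test_unphased_het_excluded_from_pairing():
    store = _store([_av(10, "0/1"), _av(20, "0|1")])
    assert find_compound_het(store, T) == []


def test_filtered_out_member_breaks_the_pair():
    store = _store([_av(10, "1|0", maf=0.05), _av(20, "0|1")])
    assert find_compound_het(store, T) == []


def test_pair_members_must_be_in_same_gene_distinct_positions():
    across = _store([_av(10, "1|0", gene="G1"), _av(20, "0|1", gene="G2")])
    assert find_compound_het(across, T) == []
    same_pos = _store([_av(10, "1|0"), _av(10, "0|1")])
    assert find_compound_het(same_pos, T) == []


def test_ch_requires_trio():
    with pytest.raises(ModeError):
        find_compound_het(_store([_av(10, "1|0")], trio=None), T)


def test_ch_invariant_under_input_order_permutation():
    variants = [_av(10, "1|0"), _av(20, "0|1"), _av(30, "0|1"),
                _av(40, "1|0", gene="G2"), _av(50, "0|1", gene="G2")]
    baseline = None
    for perm in itertools.permutations(variants):
        reports = find_compound_het(_store(perm), T)
        key = [(r.gene, tuple(v.pos for v in r.variants), r.inheritance)
               for r in reports]
        if baseline is None:
            baseline = key
        assert key == baseline
    assert len(baseline) == 3  # G1: (10,20), (10,30); G2: (40,50)


# ---------------------------------------------------------------------------
# hom alt / de novo


def test_hom_alt_reported_and_het_not():
    store = _store([_av(10, "1|1", father="0/1", mother="0/1"),
                    _av(20, "0|1", father="0/1", mother="0/1")])
    (rep,) = find_hom_alt(store, T, require_carrier_parents=False)
    assert rep.kind == "hom_alt" and rep.variants[0].pos == 10


def test_hom_alt_carrier_parent_mode():
    store = _store([_av(10, "1/1", father="0/0", mother="0/1")])
    assert len(find_hom_alt(store, T, require_carrier_parents=False)) == 1
    assert find_hom_alt(store, T, require_carrier_parents=True) == []


def test_de_novo_definition_and_fail_closed_on_missing_parent():
    denovo = _av(10, "0/1", father="0/0", mother="0/0")
    inherited = _av(20, "0/1", father="0/1", mother="0/0")
    missing_dad = _av(30, "0/1", father="./.", mother="0/0")
    store = _store([denovo, inherited, missing_dad])
    reports = find_de_novo(store, T)
    assert [r.variants[0].pos for r in reports] == [10]
    assert reports[0].inheritance == ("undetermined",)


def test_de_novo_requires_trio():
    with pytest.raises(ModeError):
        find_de_novo(_store([_av(10, "0/1")], trio=None), T)


def test_no_filter_leakage(pipeline_vcf):
    """Every reported variant passes the filters it was selected under."""
    for kind, reports in pipeline_vcf["reports"].items():
        for rep in reports:
            for v in rep.variants:
                assert passes_filters(v, T)


# ---------------------------------------------------------------------------
# monotonicity


def test_threshold_monotonicity_on_fixture(fx_vcf, tmp_path_factory):
    """Stricter thresholds never increase report counts, for any kind."""
    from comphet.vcf_io import read_vcf
    from conftest import run_fixture_pipeline
    out = tmp_path_factory.mktemp("mono")
    summary = run_fixture_pipeline(fx_vcf, out)
    records, _ = read_vcf(out / "normalized.vcf")
    trio = TrioContext(child_id="CHILD", father_id="FATHER", mother_id="MOTHER")
    store = build_store(records, trio=trio)

    mafs = [0.05, 0.01, 0.005, 0.001, 0.0]
    cadds = [0.0, 10.0, 15.0, 20.0, 40.0]
    grid = {}
    for maf, cadd in itertools.product(mafs, cadds):
        t = FilterThresholds(maf_max=maf, cadd_min=cadd)
        grid[(maf, cadd)] = (
            len(find_compound_het(store, t)),
            len(find_hom_alt(store, t)),
            len(find_de_novo(store, t)),
        )
    for i, maf in enumerate(mafs):
        for j, cadd in enumerate(cadds):
            if i + 1 < len(mafs):  # stricter maf bound
                assert all(x >= y for x, y in
                           zip(grid[(maf, cadd)], grid[(mafs[i + 1], cadd)]))
            if j + 1 < len(cadds):  # stricter cadd bound
                assert all(x >= y for x, y in
                           zip(grid[(maf, cadd)], grid[(maf, cadds[j + 1])]))


# ---------------------------------------------------------------------------
# GDI


def _packaged_gdi():
    with resources.as_file(
            resources.files("comphet.data") / "gdi_excerpt.tsv") as p:
        return load_gdi_table(p)


def test_gdi_classification_thresholds():
    """Low-GDI genes (6.2) classify as likely disease-damage candidates;
    high-GDI genes (42.9) do not."""
    gdi = _packaged_gdi()
    reports = [  # one per gene in the packaged excerpt
        find_compound_het(_store([_av(10, "1|0", gene=g), _av(20, "0|1", gene=g)]), T)[0]
        for g in ("FLNB", "TTN", "TBC1D2", "TOX2")
    ]
    annotated = annotate_gdi(reports, gdi)
    classes = {r.gene: (r.gdi.gdi_score, r.gdi.damage_class) for r in annotated}
    assert classes["FLNB"] == (6.2, "likely")
    assert classes["TTN"] == (42.9, "unlikely")
    assert classes["TBC1D2"] == (9.7, "likely")
    assert classes["TOX2"] == (4.4, "likely")


def test_gdi_join_is_case_insensitive_and_left():
    gdi = {"flnb": 6.2}
    (rep,) = annotate_gdi(
        [find_hom_alt(_store([_av(10, "1|1", gene="FLNB")]), T)[0]], gdi)
    assert rep.gdi.damage_class == "likely"
    (missing,) = annotate_gdi(
        [find_hom_alt(_store([_av(10, "1|1", gene="NOVEL1")]), T)[0]], gdi)
    assert missing.gdi is None  # report retained with null GDI
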