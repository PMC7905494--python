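import pytest

from comphet.pipeline import PipelineConfig, run_pipeline
from comphet.synth_fixtures import FixtureSpec, simulate


FIXTURE_SEED = 11


@pytest.fixture(scope="session")
def fx_vcf(tmp_path_factory):
    """Default synthetic trio in plain-VCF mode (all planted categories)."""
    out = tmp_path_factory.mktemp("fx_vcf")
    return simulate(FixtureSpec(seed=FIXTURE_SEED), out, mode="vcf")


@pytest.fixture(scope="session")
def fx_gvcf(tmp_path_factory):
    """Same trio expressed as gVCFs with <NON_REF> reference blocks."""
    out = tmp_path_factory.mktemp("fx_gvcf")
    return simulate(FixtureSpec(seed=FIXTURE_SEED), out, mode="gvcf")


def run_fixture_pipeline(paths, out_dir, mode="vcf", **overrides):
    cfg = PipelineConfig(
        vcf_child=str(paths["child"]),
        vcf_father=str(paths["father"]),
        vcf_mother=str(paths["mother"]),
        ped=str(paths["ped"]),
        fasta=str(paths["fasta"]),
        out_dir=str(out_dir),
        mode=mode,
        gdi_table=str(paths["gdi"]),
        length_table=str(paths["gene_lengths"]),
        **overrides,
    )
    return run_pipeline(cfg)


@pytest.fixture(scope="session")
def pipeline_vcf(fx_vcf, tmp_path_factory):
    """Full pipeline summary (incl. report objects) on the VCF-mode trio."""
    out = tmp_path_factory.mktemp("pipe_vcf")
    return run_fixture_pipeline(fx_vcf, out)
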