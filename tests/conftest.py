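import pytest

from lncscape.pipeline import load_config, run_pipeline, write_default_config
from lncscape.synthetic_data import SimConfig, simulate, write_fixture


def tx(tid="t1", gene=None, chrom="c1", strand="+", exons=((101, 200),),
       biotype="candidate"):
    from lncscape.io_formats import TranscriptModel
    return TranscriptModel(
        transcript_id=tid, gene_id=gene or f"g_{tid}", chrom=chrom,
        strand=strand, exons=[tuple(e) for e in exons], biotype=biotype,
    )


@pytest.fixture(scope="session")
def bundle():
    """The default seeded synthetic dataset with planted truth."""
    return simulate(SimConfig(seed=1))


@pytest.fixture(scope="session")
def fixture_dir(bundle, tmp_path_factory):
    d = tmp_path_factory.mktemp("fixture")
    write_fixture(bundle, d)
    return d


@pytest.fixture(scope="session")
def pipeline_results(fixture_dir, tmp_path_factory):
    """Full pipeline run over the written synthetic fixture."""
    out = tmp_path_factory.mktemp("pipeline_out")
    cfg_path = out / "cfg.yaml"
    write_default_config(cfg_path, fixture_dir, out / "run")
    return run_pipeline(load_config(cfg_path))
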