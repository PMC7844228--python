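import numpy as np
import pytest

from polygene.pipeline import PipelineConfig, run_pipeline
from polygene.simulate import fixture_config, make_fixture_suite

FIXTURE_SEED = 7


@pytest.fixture(scope="session")
def fixture_suite(tmp_path_factory):
    """The on-disk synthetic input suite used by end-to-end tests."""
    outdir = tmp_path_factory.mktemp("fixture")
    paths, truth = make_fixture_suite(FIXTURE_SEED, outdir, fixture_config())
    return paths, truth


@pytest.fixture(scope="session")
def pipeline_run(fixture_suite, tmp_path_factory):
    """One full pipeline run on the fixture suite, shared across tests."""
    paths, truth = fixture_suite
    outdir = tmp_path_factory.mktemp("pipeline_out")
    cfg = PipelineConfig(
        sumstats=str(paths["sumstats"]),
        genes=str(paths["genes"]),
        annotations=str(paths["annotations"]),
        panel=str(paths["panel"]),
        eqtl=str(paths["eqtl"]),
        scores=str(paths["scores"]),
        genesets=str(paths["genesets"]),
        outdir=str(outdir),
        seed=FIXTURE_SEED,
    )
    return cfg, run_pipeline(cfg), truth


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
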