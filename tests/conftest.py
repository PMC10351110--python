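import numpy as np
import pytest

from hesimap.pipeline import PipelineConfig, run_pipeline
from hesimap.synthetic_world import WorldConfig, generate_world


@pytest.fixture(scope="session")
def default_world():
    """The default desk-scale world, seed 1 (shared; do not mutate)."""
    return generate_world(WorldConfig(seed=1))


@pytest.fixture(scope="session")
def tiny_world():
    cfg = WorldConfig(
        grid_width=24,
        grid_height=24,
        n_states=2,
        lgas_per_state=2,
        n_clusters=40,
        respondents_per_cluster=12,
        n_covariates=6,
        covariate_smoothness=3.0,
        n_facilities=8,
        seed=7,
    )
    return generate_world(cfg)


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """One full pipeline run on the default world (seed 1), shared by the
    acceptance and analysis tests."""
    outdir = tmp_path_factory.mktemp("default_run")
    cfg = PipelineConfig(seed=1)
    cfg.world.seed = 1
    summary = run_pipeline(cfg, outdir)
    return {"outdir": outdir, "summary": summary, "config": cfg}


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
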