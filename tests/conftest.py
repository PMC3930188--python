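import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_pipeline_config():
    """A desk-scale pipeline config: 181 samples, 40 probes, B=199."""
    from cidprognet.pipeline import PipelineConfig
    from cidprognet.synthetic_cohort import PlantedEdge, SyntheticConfig

    edges = tuple(
        [PlantedEdge(f"tgt_linear_{i:02d}", "linear", 1.5, 1.0) for i in range(1, 6)]
        + [PlantedEdge(f"tgt_nonmono_{i:02d}", "nonmonotone", 1.5, 1.0)
           for i in range(1, 4)]
        + [PlantedEdge(f"tgt_joint_{i:02d}", "joint_and", 1.5, 1.0)
           for i in range(1, 3)]
    )
    syn = SyntheticConfig(n_probes=40, planted_edges=edges, seed=11)
    return PipelineConfig(synthetic=syn, B=199, seed=11)


@pytest.fixture(scope="session")
def small_pipeline_result(small_pipeline_config):
    import warnings

    from cidprognet.pipeline import run_pipeline

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_pipeline(small_pipeline_config)


@pytest.fixture(scope="session")
def default_cohort():
    """Default-composition synthetic cohort with a handful of probes."""
    from cidprognet.synthetic_cohort import SyntheticConfig, generate_cohort

    cfg = SyntheticConfig(n_probes=90, seed=7)
    return generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
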