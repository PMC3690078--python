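import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from adspeech import etemp, pipeline
from adspeech.config import RunConfig
from adspeech.synth import CohortSpec, generate_cohort

settings.register_profile(
    "suite", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow], deadline=None,
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def run_config() -> RunConfig:
    return RunConfig(seed=0)


@pytest.fixture(scope="session")
def default_cohort():
    """The default 40-segment study cohort (20 CR / 4 ES / 10 IS / 6 AS, 60 s)."""
    return generate_cohort(CohortSpec(seed=0))


@pytest.fixture(scope="session")
def prepared_segments(default_cohort, run_config):
    """(segment_id, label, denoised signal) triples for the default cohort."""
    return [
        (c.segment_id, c.label, pipeline.prepare_signal(c.signal, run_config))
        for c in default_cohort
    ]


@pytest.fixture(scope="session")
def cohort_et_model(prepared_segments, run_config):
    X, y, ids = pipeline.extract_frame_training_set(prepared_segments, run_config)
    return etemp.train_et_model(X, y, ids, seed=run_config.seed)


@pytest.fixture(scope="session")
def cohort_feature_table(prepared_segments, run_config, cohort_et_model):
    """Full per-segment feature table (ssf/fd/esa/et columns + label)."""
    return pipeline.build_feature_table(prepared_segments, run_config, cohort_et_model)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
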