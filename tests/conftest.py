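import numpy as np
import pytest

from dfuseg import NetworkSpec, PhantomConfig, generate_cohort
from dfuseg.training import cases_from_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_spec():
    """4-stage network small enough for CPU unit tests; z pooled once,
    x/y pooled three times (8x32x32 patches divide evenly)."""
    return NetworkSpec(
        n_stages=4,
        channels_per_stage=(4, 8, 8, 16),
        pooling_pattern=((1, 2, 2), (2, 2, 2), (2, 2, 2)),
        deep_supervision_heads=3,
    )


@pytest.fixture(scope="session")
def phantom_cohort_dir(tmp_path_factory):
    """Four phantom cases written once per session."""
    out = tmp_path_factory.mktemp("cohort")
    ids = generate_cohort(PhantomConfig(seed=5), 4, out)
    return out, ids


@pytest.fixture(scope="session")
def preprocessed_cases_task1(phantom_cohort_dir):
    out, _ = phantom_cohort_dir
    loaded = cases_from_cohort(out, "task1_single")
    return {cid: d["case"] for cid, d in loaded.items()}


@pytest.fixture(scope="session")
def preprocessed_cases_task2(phantom_cohort_dir):
    out, _ = phantom_cohort_dir
    loaded = cases_from_cohort(out, "task2_dfunet")
    return {cid: d["case"] for cid, d in loaded.items()}
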