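import numpy as np
import pytest

from cognistack import PipelineConfig, run_nested_cv
from cognistack.simulate import CohortSpec, discovery_cohort_spec, generate_cohort


@pytest.fixture(scope="session")
def fast_config():
    """Reduced CV geometry used throughout the unit tests."""
    return PipelineConfig(
        outer_folds=3,
        outer_repetitions=1,
        inner_folds=3,
        inner_repetitions=2,
        c_grid=(0.25, 1.0),
        max_features=3,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_spec():
    return discovery_cohort_spec(
        "c1", "HC", "PAT", 40, 30, n_features={"cognitive": 8, "sociocognitive": 6}, seed=1
    )


@pytest.fixture(scope="session")
def small_table(small_spec):
    table, _ = generate_cohort(small_spec)
    return table


@pytest.fixture(scope="session")
def small_truth(small_spec):
    _, truth = generate_cohort(small_spec)
    return truth


@pytest.fixture(scope="session")
def nested_result(small_table, fast_config):
    """One shared nested-CV run reused by engine/inference tests."""
    return run_nested_cv(small_table, "cognitive", fast_config)


def null_cohort_spec(n_per_group: int, n_features: int, seed: int, **kw) -> CohortSpec:
    """Case-control cohort with no signal at all (all effects zero)."""
    defaults = dict(block_correlation=0.2, missing_rate=0.05)
    defaults.update(kw)
    return CohortSpec(
        cohort="null",
        n_per_group={"HC": n_per_group, "PAT": n_per_group},
        group_labels={"HC": "control", "PAT": "case"},
        group_effect={"HC": 0.0, "PAT": 0.0},
        n_features={"cognitive": n_features},
        effect_sizes={"cognitive": np.zeros(n_features)},
        seed=seed,
        **defaults,
    )
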