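import numpy as np
import pytest

from vepbench import assay, fixtures, synthetic


@pytest.fixture(scope="session")
def activity_fixture():
    return fixtures.load_activity_fixture()


@pytest.fixture(scope="session")
def activity_records():
    return fixtures.activity_records()


@pytest.fixture(scope="session")
def classification_fixture():
    return fixtures.load_classification_fixture()


@pytest.fixture(scope="session")
def evaluation_set(activity_records):
    return assay.build_evaluation_set(activity_records)


@pytest.fixture(scope="session")
def truth_and_labels(activity_fixture):
    truth = dict(zip(activity_fixture["variant"], activity_fixture["mean_rwt"]))
    labels = dict(zip(activity_fixture["variant"], activity_fixture["luciferase_label"]))
    return truth, labels


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_assay():
    """Compact synthetic assay: fast, noisy, deterministic."""
    config = synthetic.SyntheticConfig(
        n_variants=12, n_bio_reps_total=8, bio_reps_per_variant=(3, 5),
        noise_sd=0.08, seed=7,
    )
    table, truth = synthetic.generate_assay(config)
    return config, table, truth


@pytest.fixture(scope="session")
def noiseless_assay():
    config = synthetic.SyntheticConfig(
        n_variants=10, n_bio_reps_total=6, bio_reps_per_variant=(3, 4),
        noise_sd=0.0, seed=11,
    )
    table, truth = synthetic.generate_assay(config)
    return config, table, truth
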