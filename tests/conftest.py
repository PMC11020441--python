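import pandas as pd
import pytest

from aneuml import features, labeling, modeling, synthetic

#: Reduced cohort for fast unit tests; the default-size cohort is reserved
#: for the acceptance suite.
SMALL_CONFIG = dict(
    n_arms=8,
    n_contexts=6,
    genes_per_arm=(20, 40),
    n_tissues=6,
    n_organs=3,
    n_ccl_contexts=3,
    seed=7,
)


@pytest.fixture(scope="session")
def small_cohort():
    return synthetic.generate_cohort(synthetic.GeneratorConfig(**SMALL_CONFIG))


@pytest.fixture(scope="session")
def small_features(small_cohort):
    return features.build_feature_table(small_cohort.bundle)


@pytest.fixture(scope="session")
def small_labels(small_cohort):
    labels = labeling.label_table(small_cohort.records)
    return pd.Series(
        {(l.arm_id, l.context_id): l.label for l in labels}
    ).rename_axis(["arm", "context"])


@pytest.fixture(scope="session")
def default_cohort():
    return synthetic.generate_cohort(synthetic.GeneratorConfig(seed=0))


@pytest.fixture(scope="session")
def default_features_labels(default_cohort):
    labels = labeling.label_table(default_cohort.records)
    lab = pd.Series(
        {(l.arm_id, l.context_id): l.label for l in labels}
    ).rename_axis(["arm", "context"])
    table = features.build_feature_table(default_cohort.bundle)
    return table, lab


@pytest.fixture(scope="session")
def default_gain_task(default_features_labels):
    table, lab = default_features_labels
    return modeling.assemble_task(table, lab, "gain")
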