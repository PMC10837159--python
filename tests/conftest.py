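import numpy as np
import pandas as pd
import pytest

from bloodsrna import SimConfig, simulate
from bloodsrna.matrix import CountMatrix, make_sample_meta


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(
        n_donors=6,
        library_size=50_000,
        purity_fail_rate=0.05,
        outlier_rate=0.0,
        missing_content_rate=0.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    donors, samples, truth = simulate.simulate_cohort(small_config)
    records = simulate.simulate_counts(donors, samples, truth, small_config)
    return donors, samples, truth, records


@pytest.fixture(scope="session")
def small_counts(small_cohort):
    _, samples, _, records = small_cohort
    return simulate.cohort_count_matrix(samples, records)


def build_matrix(values, components, units="reads", donors=None, classes=None):
    """CountMatrix from a feature x sample array with one component label per
    sample; feature ids f0, f1, ... and sample ids s0, s1, ..."""
    values = np.asarray(values, dtype=float)
    n_feat, n_samp = values.shape
    samples = [f"s{j}" for j in range(n_samp)]
    features = [f"f{i}" for i in range(n_feat)]
    meta = make_sample_meta(
        samples,
        donors if donors is not None else [f"d{j}" for j in range(n_samp)],
        list(components),
    )
    feature_classes = None
    if classes is not None:
        feature_classes = pd.Series(list(classes), index=features)
    return CountMatrix(
        values=pd.DataFrame(values, index=features, columns=samples),
        sample_meta=meta,
        units=units,
        feature_classes=feature_classes,
    )


@pytest.fixture
def build_count_matrix():
    return build_matrix
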