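import numpy as np
import pytest

from curvhdr import pipeline, synthetic


@pytest.fixture(scope="session")
def f2_run():
    """The canonical bivariate three-population fixture, gated once.

    Session-scoped: the same run backs the pipeline unit tests and the
    cluster-recovery acceptance check.
    """
    spec = synthetic.fixture_f2()
    table, labels = synthetic.simulate_sample(spec)
    result = pipeline.curvhdr_filter(table)
    return table, synthetic.f2_merged_labels(labels), result


@pytest.fixture(scope="session")
def f1_run():
    spec = synthetic.fixture_f1()
    table, labels = synthetic.simulate_sample(spec)
    result = pipeline.curvhdr_filter(table)
    return table, labels, result


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
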