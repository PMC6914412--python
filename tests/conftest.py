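import numpy as np
import pandas as pd
import pytest

from cernanet.io_formats import ExpressionMatrix, SampleInfo
from cernanet.synthetic_data import SimulationConfig, generate


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A downsized study used by several integration tests."""
    return SimulationConfig(
        n_cohorts=2,
        samples_per_cohort=(25, 10),
        n_mRNA=200,
        n_lncRNA=60,
        n_miRNA=40,
        n_triplets=6,
        transcript_length=200,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return generate(small_config)


def toy_matrix(values, feature_class="mRNA", n_tumor=None, cohort="C1", feature_ids=None):
    """Build an ExpressionMatrix from a 2-D array; first n_tumor columns are tumor."""
    values = np.asarray(values, dtype=float)
    n_f, n_s = values.shape
    if n_tumor is None:
        n_tumor = n_s // 2
    if feature_ids is None:
        feature_ids = [f"F{i:03d}" for i in range(n_f)]
    samples = [
        SampleInfo(f"S{j:03d}", "tumor" if j < n_tumor else "normal", cohort) for j in range(n_s)
    ]
    df = pd.DataFrame(values, index=feature_ids, columns=[s.sample_id for s in samples])
    return ExpressionMatrix(
        values=df, feature_class=pd.Series(feature_class, index=df.index), samples=samples
    )
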