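import numpy as np
import pandas as pd
import pytest

import targetrank as tr


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_spec():
    """Small planted-signal scenario used across module tests."""
    return tr.SynthSpec(
        n_genes=200,
        n_pos=30,
        n_informative=5,
        n_noise=5,
        n_binary=2,
        effect=3.0,
        missing_frac=0.1,
        seed=11,
    )


@pytest.fixture
def tiny_data(tiny_spec):
    labels = tr.gen_labels(tiny_spec)
    table = tr.gen_feature_matrix(tiny_spec, labels)
    clean, _ = tr.run_preprocess(table)
    return clean, labels


def make_table(values, classes=None, genes=None):
    """Shorthand GeneFeatureTable from a dict of feature -> list."""
    df = pd.DataFrame(values)
    df.index = pd.Index(genes or [f"g{i}" for i in range(len(df))], name="Gene_Name")
    return tr.GeneFeatureTable(df, classes or {})
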