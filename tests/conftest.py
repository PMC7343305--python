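import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from nichecase import prep, synth
from nichecase.tables_io import FeatureTable


def make_table(counts, samples=None, features=None) -> FeatureTable:
    counts = np.asarray(counts)
    samples = samples or [f"s{i}" for i in range(counts.shape[0])]
    features = features or [f"f{j}" for j in range(counts.shape[1])]
    df = pd.DataFrame(counts, index=samples, columns=features)
    df.index.name, df.columns.name = "sample_id", "feature_id"
    return FeatureTable(df)


def make_metadata(status, **columns) -> pd.DataFrame:
    n = len(status)
    df = pd.DataFrame({"status": pd.Categorical(status, categories=["control", "case"])})
    df.index = pd.Index([f"s{i}" for i in range(n)], name="sample_id")
    for name, values in columns.items():
        df[name] = values
    return df


@pytest.fixture(scope="session")
def paired_tree() -> TreeNode:
    from io import StringIO

    return TreeNode.read(StringIO("((A:1,B:1):1,(C:1,D:1):1);"))


@pytest.fixture(scope="session")
def small_study():
    """A small study-like synthetic dataset shared across tests."""
    config = synth.paper_like_preset(n_cases=150, n_controls=150, k_features=120, seed=11)
    table, meta, tree, records, truth = synth.generate_dataset(config)
    return {
        "config": config,
        "table": table,
        "metadata": meta,
        "tree": tree,
        "records": records,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def small_rarefied(small_study):
    table, meta, _audit = prep.filter_samples(
        small_study["table"], small_study["metadata"], 1000, {"smoking": "former"}
    )
    rare = prep.rarefy(table, 6500, seed=3)
    return rare, meta.loc[rare.table.data.index]
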