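import logging
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

import histact as h

logging.getLogger("histact").setLevel(logging.WARNING)

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def toy_tree_data():
    """8 genes x 3 binary features with labels, from the repo fixture."""
    df = pd.read_csv(DATA / "toy_tree.tsv", sep="\t")
    X = df[["f1", "f2", "f3"]].to_numpy(dtype=np.uint8)
    y = df["label"].to_numpy()
    return X, y, ["f1", "f2", "f3"]


@pytest.fixture(scope="session")
def toy_mdr_data():
    """12 genes x 2 binary attributes with labels, from the repo fixture."""
    df = pd.read_csv(DATA / "toy_mdr.tsv", sep="\t")
    X = df[["a", "b"]].to_numpy(dtype=np.uint8)
    y = df["label"].to_numpy()
    return X, y


@pytest.fixture(scope="session")
def cd4_small():
    """A 600-gene cd4_like dataset with features and pipeline result."""
    cfg = h.cd4_like(n_genes=600, seed=7)
    ds = h.simulate_dataset(cfg)
    fm = h.build_feature_matrix(ds.signal, ds.genes)
    pr = h.derive_threshold(fm, ds.expression, k=5)
    return ds, fm, pr


@pytest.fixture(scope="session")
def cd4_medium():
    """A 2000-gene cd4_like dataset for statistics that need more genes."""
    cfg = h.cd4_like(n_genes=2000, seed=7)
    ds = h.simulate_dataset(cfg)
    fm = h.build_feature_matrix(ds.signal, ds.genes)
    pr = h.derive_threshold(fm, ds.expression, k=5)
    return ds, fm, pr
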