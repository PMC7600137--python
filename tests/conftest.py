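import numpy as np
import pandas as pd
import pytest

import breathomics as bo


@pytest.fixture(scope="session")
def default_study():
    """One simulated study at default (planted-effect) conditions."""
    table, meta, truth = bo.generate_study(bo.SimConfig(seed=7))
    return table, meta, truth


@pytest.fixture(scope="session")
def preprocessed_t0(default_study):
    """Preprocessed table + labels for the T0-vs-control contrast."""
    table, meta, truth = default_study
    qc = set(meta.loc[meta["is_qc"], "sample_id"])
    proc, report = bo.preprocess_untargeted(table, qc, seed=7)
    sel = meta[
        (meta["group"] == "control")
        | ((meta["group"] == "case") & (meta["timepoint"] == "T0"))
    ]
    sub = proc.loc[sel["sample_id"].tolist()]
    labels = pd.Series(sel["group"].to_numpy(), index=sel["sample_id"])
    return sub, labels, truth, report


@pytest.fixture()
def toy_table():
    """A tiny strictly positive feature table with known values."""
    return pd.DataFrame(
        {
            "1.00@100.0000": [2.0, 1.0, 4.0],
            "2.00@200.0000": [4.0, 2.0, 8.0],
            "3.00@300.0000": [8.0, 2.0, 16.0],
        },
        index=["s1", "s2", "s3"],
    )


def two_cluster_data(n_per_class=15, p=10, sep=4.0, seed=0):
    """Two well-separated spherical Gaussian clusters with labels."""
    rng = np.random.default_rng(seed)
    direction = rng.normal(size=p)
    direction /= np.linalg.norm(direction)
    x = np.vstack(
        [
            rng.normal(size=(n_per_class, p)) + sep * direction,
            rng.normal(size=(n_per_class, p)) - sep * direction,
        ]
    )
    labels = np.array(["a"] * n_per_class + ["b"] * n_per_class)
    return pd.DataFrame(x), labels
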