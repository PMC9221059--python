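import numpy as np
import pandas as pd
import pytest

import procoex as px


@pytest.fixture()
def toy_matrix() -> px.ExpressionMatrix:
    """4 proteins x 6 samples (4 tumor / 2 healthy) with a missing entry."""
    values = pd.DataFrame(
        [
            [1.0, 2.0, 3.0, 4.0, 1.5, 2.5],
            [2.0, np.nan, 1.0, 3.0, 2.0, 1.0],
            [0.5, 0.25, 0.75, 1.0, 0.5, 0.25],
            [5.0, 4.0, 3.0, 2.0, 1.0, 0.0],
        ],
        index=["GA", "GB", "GC", "GD"],
        columns=["T1", "T2", "T3", "T4", "H1", "H2"],
    )
    groups = pd.Series(
        ["tumor"] * 4 + ["healthy"] * 2, index=values.columns, name="group"
    )
    return px.ExpressionMatrix(values, groups)


@pytest.fixture(scope="session")
def planted_session():
    """A study-shaped nested-module dataset and its inferred network.

    105 tumor + 3 healthy samples, 180 proteins in 4 modules x 3
    submodules; shared across tests that only read from it.
    """
    cfg = px.SyntheticConfig(
        n_proteins=180, n_tumor=105, n_healthy=3, n_modules=4,
        submodules_per_module=3, module_loading=2.0, noise_sd=1.0,
        de_fraction=0.0, missing_rate=0.0, seed=0,
    )
    matrix, truth = px.generate_dataset(cfg)
    ranked = px.copula_rank_transform(matrix, seed=100)
    null = px.calibrate_null(ranked, n_perm=50_000, seed=200)
    net = px.infer_network(ranked, null, p_thresh=1e-8)
    part = px.subpartition(net, px.detect_communities(net))
    return {
        "config": cfg, "matrix": matrix, "truth": truth, "ranked": ranked,
        "null": null, "net": net, "partition": part,
    }
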