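import numpy as np
import pandas as pd
import pytest

from cnpath.datatypes import CompoundMatrix
from cnpath.network import build_network, detect_communities
from cnpath.preprocess import impute_missing, log_transform
from cnpath.simulate import SyntheticConfig, simulate_study


@pytest.fixture(scope="session")
def default_study():
    """Full-size synthetic study at default conditions, seed 1."""
    return simulate_study(SyntheticConfig(seed=1))


@pytest.fixture(scope="session")
def processed_default(default_study):
    compounds, _, _, _ = default_study
    return impute_missing(log_transform(compounds))


@pytest.fixture(scope="session")
def bench_study():
    """Strong-structure benchmark conditions: loading 0.95, noise 0.1."""
    cfg = SyntheticConfig(seed=1, community_loading=0.95, noise_sd=0.1)
    return cfg, simulate_study(cfg)


@pytest.fixture(scope="session")
def bench_network(bench_study):
    _, (compounds, _, _, _) = bench_study
    processed = impute_missing(log_transform(compounds))
    net = build_network(processed)
    partition = detect_communities(net)
    return processed, net, partition


def toy_matrix(values: np.ndarray, n_groups: int = 2, reps: int = 3) -> CompoundMatrix:
    """Compound matrix with one accession and ``n_groups`` treatments."""
    n = n_groups * reps
    assert values.shape[0] == n
    samples = pd.DataFrame(
        {
            "accession": ["a1"] * n,
            "treatment": [f"t{g}" for g in range(n_groups) for _ in range(reps)],
            "replicate": list(range(1, reps + 1)) * n_groups,
        },
        index=pd.Index([f"s{i}" for i in range(n)], name="sample"),
    )
    cols = [f"c{j}" for j in range(values.shape[1])]
    return CompoundMatrix(
        pd.DataFrame(values, index=samples.index, columns=cols),
        samples,
        pd.Series("unknown", index=cols),
    )
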