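import numpy as np
import pandas as pd
import pytest

import ipf
from ipf.config import RunConfig
from ipf.integrate import build_embedding
from ipf.preprocess import standardize


def small_config(seed: int = 1, **kw) -> RunConfig:
    """Desk-scale settings: coarse grid, few references, small k scan."""
    base = dict(grid_n=12, k_max=5, gap_B=10, seed=seed)
    base.update(kw)
    return RunConfig(**base)


@pytest.fixture(scope="session")
def three_cluster_sim():
    """One simulated source with 3 well-separated clusters (n=90, p=40)."""
    spec = ipf.SimSpec(
        n_samples=90,
        k_true=3,
        effect_size=3.0,
        noise_fraction=0.3,
        omics_specs=[ipf.OmicsSpec(n_features=40)],
        seed=1,
    )
    return ipf.simulate(spec)


@pytest.fixture(scope="session")
def fitted_pipeline(three_cluster_sim):
    """Standardized source + shared embedding + smoothed profiles + solution."""
    cfg = small_config(seed=1)
    std = standardize(three_cluster_sim.datasets[0])
    embedding, values = build_embedding([std], cfg)
    trained = ipf.fit_source(embedding, values["omics1"], cfg, "omics1")
    return {
        "config": cfg,
        "std": std,
        "embedding": embedding,
        "trained": trained,
        "truth": three_cluster_sim.true_labels,
    }


@pytest.fixture()
def mixed_dataset():
    """Small clinical-style table with every variable type and a missing cell."""
    rng = np.random.default_rng(7)
    n = 40
    cont = rng.normal(size=n)
    ordi = np.floor(rng.uniform(0, 4, size=n))
    bina = (rng.uniform(size=n) > 0.5).astype(float)
    cate = rng.integers(0, 3, size=n).astype(float)
    cont2 = cont * 0.8 + 0.6 * rng.normal(size=n)
    df = pd.DataFrame(
        {"age": cont, "stage": ordi, "smoker": bina, "site": cate, "fev1": cont2},
        index=[f"s{i:02d}" for i in range(n)],
    )
    df.iloc[0, 0] = np.nan
    types = pd.Series(
        ["continuous", "ordinal", "binary", "categorical", "continuous"],
        index=df.columns,
    )
    return ipf.OmicsDataset("clinical", df, types)
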