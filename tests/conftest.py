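import numpy as np
import pandas as pd
import pytest

import sortmet as sm


@pytest.fixture
def small_matrix() -> sm.IntensityMatrix:
    data = pd.DataFrame(
        {
            "s1": [100.0, 0.0, 4.0],
            "s2": [110.0, 5.0, 8.0],
            "s3": [90.0, 6.0, 0.0],
        },
        index=["m1", "m2", "m3"],
    )
    return sm.IntensityMatrix(data)


@pytest.fixture
def two_group_meta() -> list[sm.SampleMeta]:
    return [
        sm.SampleMeta(f"A{i}", "cell", group="A", pair=f"p{i}") for i in range(1, 5)
    ] + [
        sm.SampleMeta(f"B{i}", "cell", group="B", pair=f"p{i}") for i in range(1, 5)
    ]


@pytest.fixture
def simulated():
    cfg = sm.SimConfig(seed=42)
    return sm.simulate_experiment(cfg)


def random_results(rng: np.random.Generator, n: int = 50) -> pd.DataFrame:
    """A syntactically valid differential result table with random values."""
    log2_fc = rng.normal(0, 2, n)
    p = rng.uniform(0, 1, n)
    # plant a handful of clear calls so significant sets are nonempty
    strong = rng.choice(n, size=min(n, max(3, n // 10)), replace=False)
    p[strong] = rng.uniform(0, 1e-8, strong.size)
    log2_fc[strong] = rng.choice([-1, 1], strong.size) * rng.uniform(2, 4, strong.size)
    fdr = sm.benjamini_hochberg(p)
    return pd.DataFrame(
        {
            "metabolite_id": [f"m{i}" for i in range(n)],
            "mean_ref": rng.normal(10, 2, n),
            "mean_test": rng.normal(10, 2, n),
            "log2_fc": log2_fc,
            "fold_change": np.exp2(log2_fc),
            "p_value": p,
            "fdr": fdr,
            "significant": (np.exp2(np.abs(log2_fc)) > 2) & (fdr < 0.05),
        }
    )
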