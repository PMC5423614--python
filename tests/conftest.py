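import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def ko_experiment():
    """Factory for seeded default synthetic knockout experiments (cached)."""
    from highedges.simulate import generate_ko_experiment

    cache = {}

    def make(seed=0, **kwargs):
        key = (seed, tuple(sorted(kwargs.items())))
        if key not in cache:
            cache[key] = generate_ko_experiment(seed=seed, **kwargs)
        return cache[key]

    return make


@pytest.fixture()
def stats_frame():
    """Factory for small per-gene statistics tables."""

    def make(rows):
        # rows: {gene: (log2fc, p_value)}
        genes = list(rows)
        return pd.DataFrame(
            {
                "log2fc": [rows[g][0] for g in genes],
                "t_stat": np.nan,
                "p_value": [rows[g][1] for g in genes],
                "df_total": np.nan,
            },
            index=pd.Index(genes, name="gene"),
        )

    return make
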