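import numpy as np
import pandas as pd
import pytest

from gxsex import SimConfig, simulate_cohort


def make_sumstats(n, seed=0, se_m=0.1, se_f=0.1):
    """A well-formed synthetic summary-statistics table."""
    rng = np.random.default_rng(seed)
    width = len(str(n))
    return pd.DataFrame({
        "snp_id": [f"snp{i:0{width}d}" for i in range(n)],
        "chrom": "1",
        "pos": np.arange(1, n + 1),
        "effect_allele": "A",
        "other_allele": "G",
        "p": rng.uniform(0.05, 0.95, n),
        "beta_m": rng.normal(0, 1, n),
        "se_m": se_m,
        "n_m": 10000,
        "beta_f": rng.normal(0, 1, n),
        "se_f": se_f,
        "n_f": 10000,
    })


@pytest.fixture(scope="session")
def small_cohort():
    """Equal-effects cohort shared by fast unit tests."""
    cfg = SimConfig(n_individuals=4000, n_snps=300, n_causal=150, h2_m=0.5)
    return simulate_cohort(cfg, seed=11)
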