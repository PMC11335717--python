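import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from medmr import HarmonizedSet, SimConfig, SummaryStatsTable, simulate_three_trait_gwas

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def make_table(trait_id="trait", n=10, seed=0, trait_type="quantitative"):
    """Small random but valid summary-statistics table."""
    rng = np.random.default_rng(seed)
    bases = ["A", "C", "G", "T"]
    ea, oa = [], []
    for _ in range(n):
        pair = rng.choice(4, size=2, replace=False)
        ea.append(bases[pair[0]])
        oa.append(bases[pair[1]])
    se = rng.uniform(0.01, 0.05, n)
    beta = rng.normal(0, 0.1, n)
    from scipy import stats as st

    df = pd.DataFrame(
        {
            "snp_id": [f"rs{i}" for i in range(1, n + 1)],
            "chrom": [str(i % 22 + 1) for i in range(n)],
            "pos_bp": np.arange(1, n + 1) * 100_000,
            "effect_allele": ea,
            "other_allele": oa,
            "eaf": rng.uniform(0.05, 0.95, n),
            "beta": beta,
            "se": se,
            "pval": 2 * st.norm.sf(np.abs(beta / se)),
            "n": 10_000,
        }
    )
    return SummaryStatsTable(trait_id, trait_type, df)


def make_harmonized(n=10, seed=0, beta=0.2, noise=True, sx=0.01, sy=0.02):
    """Harmonized set generated under Gamma = beta*gamma (+ noise)."""
    rng = np.random.default_rng(seed)
    g = rng.uniform(0.05, 0.3, n)
    G = beta * g + (rng.normal(0, sy, n) if noise else 0.0)
    df = pd.DataFrame(
        {
            "snp_id": [f"rs{i}" for i in range(1, n + 1)],
            "gamma_hat": g,
            "sigma_x": sx,
            "Gamma_hat": G,
            "sigma_y": sy,
        }
    )
    return HarmonizedSet("exp", "out", df)


@pytest.fixture
def small_table():
    return make_table()


@pytest.fixture
def sim_bundle():
    """One simulated three-trait study at the default design."""
    cfg = SimConfig(seed=1)
    return simulate_three_trait_gwas(cfg)


@pytest.fixture
def clean_harmonized(sim_bundle):
    """Truth instruments of the default simulation, harmonized X vs Y."""
    from medmr import harmonize

    x, _, y, _, truth = sim_bundle
    return harmonize(x, y, truth.instrument_ids)
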