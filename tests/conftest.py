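import numpy as np
import pandas as pd
import pytest

from mrlab import SimConfig, make_ld_panel
from mrlab.sumstats import SumStats


@pytest.fixture(scope="session")
def small_panel():
    """10 blocks of 5 variants, rho=0.5, no palindromic alleles."""
    cfg = SimConfig(n_blocks=10, block_size=5, rho=0.5, palindrome_fraction=0.0, seed=11)
    return make_ld_panel(cfg)


@pytest.fixture(scope="session")
def desk_config():
    """Desk-scale individual-level simulation design."""
    return SimConfig(n_blocks=25, block_size=20, n_x=8000, n_y=8000,
                     causal_fraction=0.05, seed=7)


def make_sumstats(rows, trait="trait"):
    """Build a SumStats from a list of row dicts, filling defaults."""
    defaults = dict(chrom="1", pos=0, effect_allele="A", other_allele="G",
                    eaf=0.3, beta=0.1, se=0.02, pvalue=1e-6, n=10000)
    full = []
    for i, r in enumerate(rows):
        d = dict(defaults)
        d.setdefault("variant_id", f"rs{i + 1}")
        d["pos"] = 1000 * (i + 1)
        d.update(r)
        full.append(d)
    df = pd.DataFrame(full)
    df["z"] = df["beta"] / df["se"]
    return SumStats(trait_label=trait, table=df)


@pytest.fixture
def rng():
    return np.random.default_rng(123)
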