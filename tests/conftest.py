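import numpy as np
import pandas as pd
import pytest

from mrscreen.estimators import MRInput
from mrscreen.simulate import SimConfig, simulate_pair
from mrscreen.sumstats import SumStatsTable, harmonize


def mri_from_config(cfg: SimConfig) -> MRInput:
    """Harmonized MRInput using every simulated variant as an instrument."""
    exposure, outcome, _, _ = simulate_pair(cfg)
    pair = harmonize(exposure, outcome)
    u = pair.usable()
    return MRInput(
        u["b_X"].to_numpy(), u["se_X"].to_numpy(),
        u["b_Y"].to_numpy(), u["se_Y"].to_numpy(),
        variant_ids=list(u["variant_id"]),
    )


def table_from_records(rows, trait_id="t", trait_type="continuous") -> SumStatsTable:
    defaults = dict(chrom="1", pos=1, eaf=0.3, n=10000, n_case=np.nan, n_control=np.nan)
    full = []
    for i, r in enumerate(rows):
        rec = {"variant_id": f"rs{i}", "effect_allele": "A", "other_allele": "G",
               **defaults, **r}
        full.append(rec)
    columns = ["variant_id", "chrom", "pos", "effect_allele", "other_allele",
               "eaf", "beta", "se", "pval", "n", "n_case", "n_control"]
    df = pd.DataFrame(full, columns=columns)
    return SumStatsTable(trait_id, trait_type, df)


@pytest.fixture(scope="session")
def causal_pair():
    return simulate_pair(SimConfig(L_total=50, gamma=0.3, seed=102))


@pytest.fixture(scope="session")
def null_pair():
    return simulate_pair(SimConfig(L_total=50, seed=101))
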