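import numpy as np
import pandas as pd
import pytest

from cellmr import PipelineConfig, ReferencePanel, RegionSumStats
from cellmr.synthetic_data import ScenarioSpec, simulate_panel


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def config():
    return PipelineConfig()


@pytest.fixture
def small_panel():
    """40-variant, 500-individual block-LD panel (blocks of 10, rho=0.8)."""
    spec = ScenarioSpec(scenario="null", n_variants=40, block_size=10,
                        rho=0.8, n_ref=500, seed=11)
    return simulate_panel(spec)


def region_from_arrays(pos, beta, se, chrom="1", n=1000, trait_type="quantitative",
                       ea="A", oa="G", eaf=0.3, **meta) -> RegionSumStats:
    """Small helper to build a region from plain arrays."""
    m = len(pos)
    df = pd.DataFrame({
        "chrom": chrom, "pos": pos, "rsid": [f"rs{p}" for p in pos],
        "ea": ea, "oa": oa, "eaf": eaf, "beta": beta, "se": se,
        "n": n,
    })
    return RegionSumStats(trait_id=meta.pop("trait_id", "t"),
                          trait_type=trait_type, df=df, **meta)
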