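import numpy as np
import pandas as pd
import pytest

from rsomics.datamodel import BetaMatrix, MValueMatrix, SampleSheet
from rsomics.simulate import SimulationConfig, make_gold_cohort, simulate_methylation


@pytest.fixture(scope="session")
def small_bundle():
    """Full small cohort (methylation + expression) shared across tests."""
    return make_gold_cohort("small", seed=11)


@pytest.fixture(scope="session")
def planted_cpg_bundle():
    """Methylation-only cohort: 50 planted CLL/DLBCL CpGs, 30 IGHV CpGs, 920 null."""
    cfg = SimulationConfig(
        seed=23,
        n_cpgs=1000,
        frac_cll_dlbcl_differential=0.05,
        delta_beta_effect=0.40,
        frac_ighv_differential=0.03,
        n_cll_u=20, n_cll_m=20, n_dlbcl=40,
        n_rs_cll_like=5, n_rs_dlbcl_like=5,
        n_promoter_genes=0, n_correlated_promoters=0,
    )
    return simulate_methylation(cfg)


@pytest.fixture
def two_group_sheet():
    def _make(n1: int, n2: int, g1: str = "CLL", g2: str = "DLBCL"):
        ids = [f"a{i}" for i in range(n1)] + [f"b{i}" for i in range(n2)]
        return SampleSheet(
            pd.DataFrame({"sample_id": ids, "group": [g1] * n1 + [g2] * n2})
        ), ids

    return _make


@pytest.fixture
def random_mvalues(two_group_sheet):
    rng = np.random.default_rng(5)
    sheet, ids = two_group_sheet(6, 6)
    vals = rng.normal(0, 1, size=(20, 12))
    m = MValueMatrix(pd.DataFrame(vals, index=[f"f{i}" for i in range(20)], columns=ids))
    return m, sheet


@pytest.fixture
def beta_matrix():
    rng = np.random.default_rng(9)
    vals = rng.uniform(0.05, 0.95, size=(8, 6))
    return BetaMatrix(
        pd.DataFrame(vals, index=[f"cg{i}" for i in range(8)],
                     columns=[f"s{i}" for i in range(6)])
    )
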