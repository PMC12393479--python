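import anndata as ad
import numpy as np
import pandas as pd
import pytest


def make_adata(X, cell_types, groups=None, genes=None):
    """Small dense AnnData with cell_type/group labels."""
    X = np.asarray(X, dtype=float)
    n, g = X.shape
    if genes is None:
        genes = [f"g{j + 1}" for j in range(g)]
    obs = pd.DataFrame(
        {"cell_type": list(cell_types),
         "group": list(groups) if groups is not None else ["G"] * n},
        index=[f"c{i + 1}" for i in range(n)],
    )
    return ad.AnnData(X=X, obs=obs, var=pd.DataFrame(index=list(genes)))


@pytest.fixture
def raw_activity_fixture():
    """12-row activity table with one violation of each QC rule.

    7 clean unique records + 2 exact duplicates + 1 PAINS row + 1 row over
    the 1 mM cutoff + 1 within-pair outlier.
    """
    from scfumes.simulate import SimConfig, simulate_activity

    cfg = SimConfig(seed=99, n_cell_types=2, n_genes=10, n_sensor_genes=5)
    records = simulate_activity(cfg, None, n_duplicate_rows=2, n_pains_rows=1,
                                n_over_cutoff_rows=1, n_outlier_rows=1,
                                records_per_pair=(1, 2))
    assert len(records) == 12  # 7 base records under this seed
    return records
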