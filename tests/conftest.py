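import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

import ripqtl as r
from ripqtl.tmt import trimmed_location

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_panel():
    """A small RI panel with planted cis effects, shared across tests."""
    cfg = r.SimConfig(
        n_strains=28, n_chromosomes=5, markers_per_chr=50, chr_length_cM=25,
        n_proteins=100, n_cis_effects=20, n_trans_effects=0,
        cis_effect_size=1.0, polygenic_sd=0.0, residual_sd=0.5,
        sex_effect_sd=0.0, batch_effect_sd=0.0, seed=11,
    )
    g = r.simulate_ri_genotypes(cfg)
    pm, truth = r.simulate_proteome(g, cfg)
    return cfg, g, pm, truth


@pytest.fixture(scope="session")
def small_kinship(small_panel):
    _, g, _, _ = small_panel
    return r.kinship(g)


def balanced_proteome(cfg: "r.SimConfig", trim: float = 0.1):
    """Simulated proteome whose per-channel trimmed locations are equalised.

    Channel normalization estimates a per-channel offset from the PSM
    population; exact pipeline inversion is only possible when the true
    matrix carries no such offsets, so round-trip fixtures balance the
    columns first.
    """
    g = r.simulate_ri_genotypes(cfg)
    pm, truth = r.simulate_proteome(g, cfg)
    vals = pm.values.to_numpy()
    offsets = np.array([trimmed_location(vals[:, j], trim) for j in range(vals.shape[1])])
    vals = vals - (offsets - offsets.mean())[None, :]
    pm_bal = r.ProteinMatrix(pd.DataFrame(vals, index=pm.values.index, columns=pm.values.columns),
                             pm.samples)
    return g, pm_bal, truth
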