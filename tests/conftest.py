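import numpy as np
import pytest

from lymphtraj.synthdata import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def balanced5_run():
    """Two-cohort run with five balanced, well-separated cell types.

    Shared by clustering/annotation tests; no empties or doublets so every
    barcode is a true singlet.
    """
    types5 = ["B naive", "CD4 TCM", "CD8 TEM", "NK", "MAIT"]
    props = {c: {t: 0.2 for t in types5} for c in ("HS", "RAP")}
    cfg = SimConfig(
        seed=11, n_empty_droplets=0, doublet_rate=0.0, cohorts=("HS", "RAP"),
        donors_per_cohort=4, cells_per_donor=250, celltype_props=props,
    )
    return (cfg,) + simulate_cohort(cfg)


@pytest.fixture(scope="session")
def rapcci_run():
    """RAP-vs-CCI run with planted condition effects and exhaustion shift."""
    cfg = SimConfig(
        seed=31, n_empty_droplets=0, doublet_rate=0.0, cohorts=("RAP", "CCI"),
        donors_per_cohort=4, cells_per_donor=400,
    )
    return (cfg,) + simulate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
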