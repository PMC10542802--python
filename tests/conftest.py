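import pathlib

import numpy as np
import pandas as pd
import pytest

from hetburden import load_gene_map
from hetburden.constraint import SiteFrequencyDB, positional_scores, window_oe
from hetburden.simulate import SimConfig, gen_cohort, gen_constraint_db

DATA_DIR = pathlib.Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def genemap():
    return load_gene_map()


@pytest.fixture(scope="session")
def sim_bundle(genemap):
    """A small end-to-end simulation shared across tests."""
    config = SimConfig(n_samples=2_000)
    db = gen_constraint_db(genemap, config, seed=1)
    track = positional_scores(window_oe(db, genemap, k=30))
    cohort, calls, metrics = gen_cohort(config, genemap, track, seed=2)
    return {"config": config, "db": db, "track": track,
            "cohort": cohort, "calls": calls, "metrics": metrics}


def toy_site_db(genome_length: int = 200, seed: int = 0,
                mean_obs: float = 2.0) -> SiteFrequencyDB:
    """Random complete site-frequency table for a toy circular genome."""
    rng = np.random.default_rng(seed)
    rows = []
    for pos in range(1, genome_length + 1):
        ref = "ACGT"[rng.integers(4)]
        for alt in "ACGT":
            if alt != ref:
                rows.append((pos, ref, alt, int(rng.poisson(mean_obs)),
                             float(rng.uniform(0.5, 3.0))))
    table = pd.DataFrame(rows, columns=SiteFrequencyDB.COLUMNS)
    return SiteFrequencyDB(table, genome_length)
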