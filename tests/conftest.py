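import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from diapop.simulate import (
    SimulationConfig,
    simulate_annotation,
    simulate_pooled_reads,
    simulate_splice_experiment,
)

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        seed=42,
        n_genes=60,
        replicates=3,
        diapause_days=(0, 3, 6),
        direct_days=(0, 3),
        pool_sizes={"kullaberg": 24, "lulea": 30},
        mean_coverage=40.0,
        category_fractions={"Diap": 0.15, "Both": 0.1, "Dir": 0.1},
    )


@pytest.fixture(scope="session")
def small_sim(small_config):
    sim_ann = simulate_annotation(small_config)
    exon_tbl, gene_tbl, events, design = simulate_splice_experiment(small_config, sim_ann)
    pooled = simulate_pooled_reads(small_config, sim_ann)
    return {
        "config": small_config,
        "sim_ann": sim_ann,
        "exon": exon_tbl,
        "gene": gene_tbl,
        "events": events,
        "design": design,
        "pooled": pooled,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(0)
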