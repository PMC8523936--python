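"""Shared fixtures: one seeded toy-genome simulation and pipeline run.

The expensive objects (contact maps, differential-interaction table,
full pipeline results) are session-scoped so the whole suite pays for
them once.
"""

from __future__ import annotations

import numpy as np
import pytest

from hicomp import diffint, pipeline, simulate
from hicomp.genome_io import BinTable, ContactMap


@pytest.fixture(scope="session")
def sim_config() -> simulate.SimConfig:
    return simulate.SimConfig(seed=1)


@pytest.fixture(scope="session")
def truth(sim_config):
    return simulate.plant_truth(sim_config)


@pytest.fixture(scope="session")
def samples(sim_config, truth):
    sample_set, _ = simulate.simulate_contact_maps(sim_config, truth)
    return sample_set


@pytest.fixture(scope="session")
def fine_samples(sim_config, truth):
    sample_set, _ = simulate.simulate_contact_maps(sim_config, truth,
                                                   resolution="fine")
    return sample_set


@pytest.fixture(scope="session")
def genes(sim_config, truth):
    return simulate.simulate_expression(sim_config, truth)


@pytest.fixture(scope="session")
def ditable(samples):
    return diffint.di_analysis(samples)


@pytest.fixture(scope="session")
def pipeline_results(tmp_path_factory):
    config = pipeline.RunConfig(
        outdir=str(tmp_path_factory.mktemp("run")), )
    config.sim = simulate.SimConfig(seed=1)
    return pipeline.run_pipeline(config)


@pytest.fixture(scope="session")
def recovery(pipeline_results):
    return pipeline.validate_recovery(pipeline_results)


def random_contact_map(rng: np.random.Generator, n_bins: int = 50,
                       resolution: int = 500_000,
                       chroms: int = 2) -> ContactMap:
    """Small random map helper used across I/O and oracle tests."""
    per = n_bins // chroms
    bins = BinTable.from_chrom_sizes(
        {f"chr{i + 1}": per * resolution for i in range(chroms)}, resolution)
    iu = np.triu_indices(len(bins))
    counts = rng.poisson(5.0, size=len(iu[0]))
    nz = counts > 0
    return ContactMap.from_records(bins, iu[0][nz], iu[1][nz], counts[nz],
                                   warn_duplicates=False)
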