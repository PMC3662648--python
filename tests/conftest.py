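"""Shared fixtures: small simulated datasets and the default benchmark run.

Everything is generated in-process from fixed seeds; no data files.
"""

from __future__ import annotations

import numpy as np
import pytest

from pikapool.benchmark import run_default_benchmark
from pikapool.mapping import MappingPolicy, ReferenceIndex, build_pileups, map_read_set
from pikapool.simulate import (
    POOLS,
    PopulationModel,
    SequencingModel,
    generate_reference,
    simulate_pool_genotypes,
    simulate_pooled_reads,
)


@pytest.fixture(scope="session")
def small_reference():
    return generate_reference(6, 1200.0, 150.0, seed=11)


@pytest.fixture(scope="session")
def small_truth(small_reference):
    model = PopulationModel(variable_site_density=0.004, seed=12)
    return simulate_pool_genotypes(model, small_reference)


@pytest.fixture(scope="session")
def small_reads(small_truth):
    seqmodel = SequencingModel(
        mean_depth_per_pool=25.0, substitution_error_rate=0.002, seed=13
    )
    return simulate_pooled_reads(small_truth, seqmodel)


@pytest.fixture(scope="session")
def small_errorfree_reads(small_truth):
    seqmodel = SequencingModel(
        mean_depth_per_pool=20.0, substitution_error_rate=0.0, seed=14
    )
    return simulate_pooled_reads(small_truth, seqmodel)


@pytest.fixture(scope="session")
def small_pileup(small_reference, small_reads):
    index = ReferenceIndex(small_reference)
    policy = MappingPolicy()
    placements = []
    for pool in POOLS:
        p, _ = map_read_set(small_reads[pool], index, policy, pool)
        placements.extend(p)
    reads_by_id = {r.id: r for pool in POOLS for r in small_reads[pool]}
    return build_pileups(placements, reads_by_id, small_reference), placements


@pytest.fixture(scope="session")
def benchmark_result():
    """The default synthetic benchmark (shared across acceptance tests)."""
    return run_default_benchmark(seed=0)
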