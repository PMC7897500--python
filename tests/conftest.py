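"""Shared fixtures: one small error-free simulation reused across modules."""

import pytest

from lvis import align, iscall, simulate


@pytest.fixture(scope="session")
def construct():
    return simulate.random_construct(seed=11)


@pytest.fixture(scope="session")
def sim_error_free(construct):
    params = simulate.SimParams(
        n_chromosomes=2,
        chrom_length=300_000,
        n_genes=12,
        n_integrations=5,
        tsd_length=6,
        reads_per_end=2,
        error_rate=0.0,
        outward_bias=1.0,
        seed=5,
    )
    return simulate.simulate_run(params, construct)


@pytest.fixture(scope="session")
def host_index_error_free(sim_error_free):
    return align.build_index(sim_error_free.host.chromosomes)


@pytest.fixture(scope="session")
def pipeline_error_free(sim_error_free, construct, host_index_error_free):
    return iscall.run_pipeline(
        sim_error_free.reads, construct, host_index_error_free
    )
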