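"""Shared fixtures: a small simulated cohort reused across test modules.

The small cohort (12 cases, 2 controls, 200 tiles) exercises every
pipeline stage quickly; the acceptance tests build the full-size
benchmark cohorts themselves.
"""

import pytest

from conmeth.dmr import aggregate_tiles
from conmeth.sim import simulate_cohort, standard_config


def small_config(seed: int = 7):
    return standard_config(
        seed=seed,
        n_case=12,
        n_control=2,
        n_chroms=1,
        chrom_length=200_000,
        n_hyper=10,
        n_hypo=10,
        n_hyper_sporadic=8,
        n_hypo_sporadic=8,
        consistent_carriers=11,
        sporadic_carriers=4,
    )


@pytest.fixture(scope="session")
def small_fixture():
    return simulate_cohort(small_config())


@pytest.fixture(scope="session")
def small_tiles(small_fixture):
    return aggregate_tiles(small_fixture.coverage)
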