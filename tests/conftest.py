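"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import pytest

from triokit import (
    GenomeIndex,
    SimConfig,
    TRIO,
    simulate_reference,
    simulate_trio_cohort,
)


@pytest.fixture(scope="session")
def sim_cfg() -> SimConfig:
    """Desk-scale simulation: defaults except a smaller locus count."""
    return SimConfig(seed=11, n_loci=2_000, n_cohort_samples=50)


@pytest.fixture(scope="session")
def sim_data(sim_cfg):
    sequences, genome = simulate_reference(sim_cfg)
    trio_records, cohort_records, truth = simulate_trio_cohort(sim_cfg, sequences)
    return {
        "cfg": sim_cfg,
        "sequences": sequences,
        "genome": genome,
        "trio": trio_records,
        "cohort": cohort_records,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def toy_genome() -> GenomeIndex:
    return GenomeIndex(
        [("1", 1_000_000), ("2", 1_000_000), ("X", 500_000), ("Y", 100_000)]
    )


@pytest.fixture(scope="session")
def trio_ids():
    return TRIO
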